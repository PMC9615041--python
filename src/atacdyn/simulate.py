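"""Synthetic data generator for the time-course accessibility pipeline.

Emulates a yeast-scale ATAC-seq time course: ~3,500 peaks over five
sampling days (0, 3, 7, 10, 28) with replicated negative-binomial counts.
A small fraction of peaks is dynamic, following one of six smooth temporal
archetypes whose movement is concentrated in the day 0->3 and day 7->10
spans (the transitions at which selection pressure was applied and lifted),
and step-like differential effects are injected at those same transitions.
Ground truth (dynamic flags, archetype ids, per-transition log2
fold-changes, expected means) is recorded so every downstream stage can be
tested without external data.

The count model matches the assumption of the differential test:
mu_{i,j,r} = s_{j,r} * exp(b_i + f_i(t_j)), counts ~ NB(mean mu,
dispersion alpha) with Var = mu + alpha*mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CountMatrix, GenomicInterval, write_bed

# Sigmoidal "wave" parameterization of temporal progression: movement is
# concentrated around the selection-onset and selection-release days.
_WAVE_CENTERS = (1.5, 8.5)
_WAVE_WIDTH = 0.75

LOCATION_CLASSES = ("promoter-TSS", "TES", "exon", "intergenic")
TRANSCRIPT_CLASSES = ("mRNA", "tRNA", "other")


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic time course."""

    n_peaks: int = 3500
    timepoints_days: tuple[float, ...] = (0, 3, 7, 10, 28)
    n_replicates: int = 2
    frac_dynamic: float = 0.078
    n_archetypes: int = 6
    nb_dispersion: float = 0.05
    baseline_log_mean_range: tuple[float, float] = (np.log(20.0), np.log(500.0))
    effect_size_sd: float = 1.0  # log2 units, for both archetype amplitudes and steps
    size_factors: tuple[float, ...] | None = None  # None -> drawn log-uniform
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    transition_effect_pairs: tuple[tuple[float, float], ...] = ((0, 3), (7, 10))
    transition_effect_fracs: tuple[float, ...] = (0.26, 0.53)
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "promoter-TSS": 0.55,
            "exon": 0.15,
            "TES": 0.10,
            "intergenic": 0.20,
        }
    )
    dynamic_class_bias: Mapping[str, float] = field(
        default_factory=lambda: {"promoter-TSS": 2.0, "tRNA": 2.0}
    )
    n_genes: int = 2500
    frac_trna: float = 0.05
    frac_other_biotype: float = 0.10
    n_gene_sets: int = 20
    n_reversible_sets: int = 2
    replicate_batch_sd: float = 0.0  # optional replicate-specific log-scale batch effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks <= 0 or self.n_replicates <= 0 or self.n_archetypes <= 0:
            raise ValueError("n_peaks, n_replicates and n_archetypes must be positive")
        t = np.asarray(self.timepoints_days, dtype=float)
        if len(t) < 2 or not (np.diff(t) > 0).all():
            raise ValueError("timepoints_days must be strictly increasing")
        if not 0.0 <= self.frac_dynamic <= 1.0:
            raise ValueError("frac_dynamic must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.effect_size_sd <= 0:
            raise ValueError("effect_size_sd must be positive")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if (sf <= 0).any():
                raise ValueError("size factors must be strictly positive")
            if len(sf) != len(t) * self.n_replicates:
                raise ValueError("size_factors length must equal n_timepoints * n_replicates")
        if len(self.transition_effect_fracs) != len(self.transition_effect_pairs):
            raise ValueError("one effect fraction per transition pair required")
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("class_proportions must sum to 1")
        days = set(float(x) for x in t)
        for a, b in self.transition_effect_pairs:
            if float(a) not in days or float(b) not in days:
                raise ValueError(f"transition pair ({a}, {b}) not among timepoints")


def _wave(t: np.ndarray, center: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - center) / _WAVE_WIDTH))


def archetype_curves(times: Sequence[float], n_archetypes: int = 6) -> np.ndarray:
    """Evaluate the temporal archetype shapes at ``times``.

    Returns an (n_archetypes, n_times) array; each curve is mean-centered
    over the given times and scaled to unit maximum absolute value. The six
    base shapes are: monotone up, monotone down, early-up-then-flat,
    early-down-then-flat, up-then-reverse, down-then-reverse. Additional
    archetypes beyond six cycle through phase-shifted combinations.
    """
    t = np.asarray(times, dtype=float)
    w1 = _wave(t, _WAVE_CENTERS[0])
    w2 = _wave(t, _WAVE_CENTERS[1])
    base = [
        0.5 * (w1 + w2),  # monotone up
        -0.5 * (w1 + w2),  # monotone down
        w1,  # early up then flat
        -w1,  # early down then flat
        w1 - w2,  # up then reverse after the release day
        -(w1 - w2),  # down then reverse
    ]
    extra = [w2, -w2, 0.5 * w1 + w2, -(0.5 * w1 + w2)]
    shapes = (base + extra) * (1 + n_archetypes // 10)
    curves = np.stack(shapes[:n_archetypes])
    curves = curves - curves.mean(axis=1, keepdims=True)
    scale = np.abs(curves).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return curves / scale


@dataclass
class SimulatedAnnotation:
    """Toy genome: chromosome sizes, stranded gene models, gene sets."""

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end, tss, tes, biotype, exons
    gene_sets: dict[str, list[str]]


@dataclass
class SyntheticTruth:
    """Per-peak ground truth for the simulated counts."""

    table: pd.DataFrame  # peak_id indexed; flags, classes, per-pair true log2FC
    expected_means: pd.DataFrame  # peak x sample expected NB mean


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Build a deterministic toy genome with stranded genes and GMT sets.

    Genes (mRNA / tRNA / other biotypes) are laid head-to-tail with random
    intergenic gaps on a handful of chromosomes; gene sets partition the
    genes into ``n_gene_sets`` named sets.
    """
    rng = np.random.default_rng(config.seed)
    n_chroms = 4
    per_chrom = int(np.ceil(config.n_genes / n_chroms))
    records = []
    chrom_sizes: dict[str, int] = {}
    gid = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = 5000
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            u = rng.random()
            if u < config.frac_trna:
                biotype, length = "tRNA", int(rng.integers(70, 120))
            elif u < config.frac_trna + config.frac_other_biotype:
                biotype, length = "other", int(rng.integers(200, 1200))
            else:
                biotype, length = "mRNA", int(rng.integers(500, 2500))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + length
            tss, tes = (start, end) if strand == "+" else (end, start)
            records.append(
                {
                    "gene_id": f"G{gid:05d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "tss": tss,
                    "tes": tes,
                    "biotype": biotype,
                    "exons": f"{start}-{end}",
                }
            )
            gid += 1
            pos = end + int(rng.integers(2500, 6000))
        chrom_sizes[chrom] = pos + 20000
    genes = pd.DataFrame(records)

    ids = genes["gene_id"].tolist()
    perm = rng.permutation(len(ids))
    sets: dict[str, list[str]] = {}
    splits = np.array_split(perm, config.n_gene_sets)
    for k, block in enumerate(splits):
        sets[f"SET{k + 1:02d}"] = sorted(ids[i] for i in block)
    return SimulatedAnnotation(chrom_sizes, genes, sets)


def _place_peaks(
    annotation: SimulatedAnnotation, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Place peaks at promoters/TES/exons/intergenic gaps per class proportions."""
    genes = annotation.genes
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    n = config.n_peaks
    choice = rng.choice(len(classes), size=n, p=probs)
    rows = []
    gene_pool = genes.sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
    for i in range(n):
        cls = classes[choice[i]]
        g = gene_pool.iloc[i]
        width = int(rng.integers(200, 600))
        sign = 1 if g["strand"] == "+" else -1
        if cls == "promoter-TSS":
            offset = int(rng.integers(-700, 40))
            mid = g["tss"] + sign * offset
            gene_id, tclass = g["gene_id"], g["biotype"]
        elif cls == "TES":
            offset = int(rng.integers(60, 700))
            mid = g["tes"] + sign * offset
            gene_id, tclass = g["gene_id"], g["biotype"]
        elif cls == "exon":
            mid = int(rng.integers(g["start"] + 1, max(g["start"] + 2, g["end"])))
            gene_id, tclass = g["gene_id"], g["biotype"]
        else:  # intergenic: far from any gene on a fresh stretch past gene territory
            chrom_end = annotation.chrom_sizes[g["chrom"]]
            mid = int(rng.integers(chrom_end - 15000, chrom_end - 1000))
            gene_id, tclass = "", "other"
        start = max(0, mid - width // 2)
        rows.append(
            {
                "peak_id": f"peak_{i + 1:05d}",
                "chrom": g["chrom"],
                "start": start,
                "end": start + width,
                "location_class": cls,
                "transcript_class": tclass if cls != "intergenic" else "other",
                "gene_id": gene_id,
            }
        )
    return pd.DataFrame(rows).set_index("peak_id")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SimulatedAnnotation, list[GenomicInterval], CountMatrix, SyntheticTruth]:
    """Generate the full synthetic study: annotation, peaks, counts, truth."""
    annotation = simulate_annotation(config)
    rng = np.random.default_rng(config.seed + 1)
    layout = _place_peaks(annotation, config, rng)
    counts, truth = simulate_counts(annotation, layout, config)
    peaks = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), pid)
        for pid, r in layout.iterrows()
    ]
    return annotation, peaks, counts, truth


def simulate_counts(
    annotation: SimulatedAnnotation,
    layout: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw replicated NB counts for the peaks in ``layout``.

    Dynamic peaks follow amplitude-scaled archetype curves; step-like
    differential effects are injected at the configured transition pairs,
    persisting from the later day onward. Peaks mapping to "reversible"
    gene sets receive coherent opposite-signed effects at the first two
    configured transitions.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(layout)
    times = np.asarray(config.timepoints_days, dtype=float)
    n_t, n_r = len(times), config.n_replicates

    sample_rows = []
    for j, day in enumerate(times):
        for r in range(n_r):
            sample_rows.append(
                {"sample_id": f"d{day:g}_r{r + 1}", "day": day, "replicate": r + 1}
            )
    samples = pd.DataFrame(sample_rows)
    if config.size_factors is not None:
        sf = np.asarray(config.size_factors, dtype=float)
    else:
        lo, hi = np.log(config.size_factor_range[0]), np.log(config.size_factor_range[1])
        sf = np.exp(rng.uniform(lo, hi, size=n_t * n_r))

    # dynamic peaks: weighted sampling without replacement per class bias
    weights = np.ones(n)
    for cls, w in config.dynamic_class_bias.items():
        mask = (layout["location_class"] == cls) | (layout["transcript_class"] == cls)
        weights[mask.to_numpy()] *= w
    n_dyn = int(round(config.frac_dynamic * n))
    dyn_idx = np.zeros(n, dtype=bool)
    if n_dyn > 0:
        chosen = rng.choice(n, size=n_dyn, replace=False, p=weights / weights.sum())
        dyn_idx[chosen] = True

    curves = archetype_curves(times, config.n_archetypes)  # log2 scale, unit max
    archetype_id = np.full(n, -1)
    amplitude = np.zeros(n)
    archetype_id[dyn_idx] = rng.integers(0, config.n_archetypes, size=n_dyn)
    amplitude[dyn_idx] = rng.normal(0.0, config.effect_size_sd, size=n_dyn)

    # step effects per configured transition (log2 units, persist from day_b on)
    step_lfc = np.zeros((n, len(config.transition_effect_pairs)))
    for k, frac in enumerate(config.transition_effect_fracs):
        hit = rng.random(n) < frac
        step_lfc[hit, k] = rng.normal(0.0, config.effect_size_sd, size=hit.sum())

    # coherent reversible gene sets: opposite-signed effects at the first two pairs
    reversible_sets: list[str] = []
    if config.n_reversible_sets > 0 and len(config.transition_effect_pairs) >= 2:
        set_names = sorted(annotation.gene_sets)
        reversible_sets = set_names[: config.n_reversible_sets]
        for s_i, sname in enumerate(reversible_sets):
            members = set(annotation.gene_sets[sname])
            in_set = layout["gene_id"].isin(members).to_numpy()
            sign = 1.0 if s_i % 2 == 0 else -1.0
            mag = np.abs(rng.normal(config.effect_size_sd, 0.25 * config.effect_size_sd,
                                    size=int(in_set.sum())))
            step_lfc[in_set, 0] = sign * mag
            step_lfc[in_set, 1] = -sign * mag

    # log2-scale temporal profile per peak per timepoint
    log2_profile = np.zeros((n, n_t))
    if n_dyn > 0:
        log2_profile[dyn_idx] = amplitude[dyn_idx, None] * curves[archetype_id[dyn_idx]]
    for k, (_, day_b) in enumerate(config.transition_effect_pairs):
        onset = times >= float(day_b)
        log2_profile += step_lfc[:, [k]] * onset[None, :]

    b = rng.uniform(*config.baseline_log_mean_range, size=n)
    log_mu_t = b[:, None] + np.log(2.0) * log2_profile  # n x n_t, natural log

    mu = np.empty((n, n_t * n_r))
    for j in range(n_t):
        for r in range(n_r):
            col = j * n_r + r
            mu[:, col] = sf[col] * np.exp(log_mu_t[:, j])
    if config.replicate_batch_sd > 0:
        batch = rng.normal(0.0, config.replicate_batch_sd, size=n_t * n_r)
        mu = mu * np.exp(batch)[None, :]

    counts = nb_draw(mu, config.nb_dispersion, rng)
    count_df = pd.DataFrame(counts, index=layout.index, columns=samples["sample_id"].tolist())

    # per consecutive pair true log2FC (archetype movement + step injection)
    truth_cols: dict[str, np.ndarray] = {}
    for a, b_day in zip(times[:-1], times[1:]):
        ja, jb = int(np.where(times == a)[0][0]), int(np.where(times == b_day)[0][0])
        truth_cols[f"lfc_{a:g}_{b_day:g}"] = log2_profile[:, jb] - log2_profile[:, ja]
    truth_table = pd.DataFrame(
        {
            "is_dynamic": dyn_idx,
            "archetype_id": np.where(dyn_idx, archetype_id, -1),
            "amplitude": amplitude,
            "location_class": layout["location_class"].to_numpy(),
            "transcript_class": layout["transcript_class"].to_numpy(),
            "gene_id": layout["gene_id"].to_numpy(),
            **truth_cols,
        },
        index=layout.index,
    )
    truth_table.attrs["reversible_sets"] = reversible_sets
    expected = pd.DataFrame(mu, index=layout.index, columns=samples["sample_id"].tolist())
    cm = CountMatrix(count_df, samples)
    return cm, SyntheticTruth(truth_table, expected)


def nb_draw(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Draw NB counts with Var = mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu).astype(np.int64)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p).astype(np.int64)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            members = "\t".join(gene_sets[name])
            fh.write(f"{name}\tsynthetic\t{members}\n")


def write_dataset(
    outdir: str | Path,
    annotation: SimulatedAnnotation,
    peaks: Sequence[GenomicInterval],
    counts: CountMatrix,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the synthetic study to plain-text files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out / "peaks.bed",
        "genes": out / "genes.tsv",
        "gmt": out / "gene_sets.gmt",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_bed(peaks, paths["peaks"])
    annotation.genes.to_csv(paths["genes"], sep="\t", index=False)
    write_gmt(annotation.gene_sets, paths["gmt"])
    counts.write(paths["counts"], paths["samples"])
    truth.table.rename_axis("peak_id").to_csv(paths["truth"], sep="\t")
    return paths
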