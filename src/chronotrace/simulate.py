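"""Synthetic fixtures with the statistical structure the pipeline assumes.

The flagship generator emulates a transgene-barcoded developmental time
series: ten hourly samples (5–14 hpf), each marked by a unique pair drawn
from 20 sample barcodes, profiled together in one pooled scRNA-seq run.
Expression follows a branching trajectory — a founder population that
splits into two lineages at a bifurcation time — with temporally structured
gene programs (Gaussian activity bumps in real time scaled into
negative-binomial means, per-cell lognormal depth, Bernoulli dropout).
Sample-barcode UMI counts are Poisson with a shared per-cell expression
factor, so cotransfected pairs are strongly correlated across cells while
independent barcodes are not.  Companion generators produce screen
phenotype counts, division-geometry centroid sets, and a toy regulatory
fixture (gene models + motif sites + differential-accessibility table)
with planted motif enrichments.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .motifs import GeneModel

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_timeseries",
    "simulate_screen_counts",
    "simulate_division_geometry",
    "simulate_regulatory_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic time-series experiment.

    Defaults mirror the emulated experiment: 10 hourly samples spanning
    5–14 hpf, 20 barcodes in 10 designed pairs, and a founder lineage that
    bifurcates at 10 hpf.  Barcode UMI rates are free parameters (per-cell
    barcode depth is not constrained by the emulated experiment); the
    defaults give bright designed pairs over a faint ambient background,
    with enough shared per-cell reporter variability (electroporated
    transgene load varies strongly between embryos) that cotransfected
    pairs correlate above 0.98 across cells, the regime the demux QC is
    built for.
    """

    n_timepoints: int = 10
    t_start_hpf: float = 5.0
    n_cells_per_timepoint: int = 100
    n_barcodes: int = 20
    barcode_capture_rate: float = 0.9
    barcode_lambda_high: float = 20.0
    barcode_lambda_bg: float = 0.01
    mosaic_fraction: float = 0.1
    n_genes: int = 300
    n_gene_clusters: int = 8
    cluster_peak_times: tuple[float, ...] = (5.5, 6.5, 8.0, 9.5, 11.0, 12.0, 13.0, 14.0)
    bifurcation_time: float = 10.0
    maturity_window_h: float = 1.5
    bump_width_h: float = 1.2
    cell_age_jitter_h: float = 0.5
    branch_decay_h: float = 0.5
    program_amplitude: float = 8.0
    baseline_expression: float = 0.1
    nb_dispersion: float = 10.0
    dropout_rate: float = 0.1
    library_size_logsd: float = 0.3
    barcode_factor_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("barcode_capture_rate", "mosaic_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_barcodes % 2 != 0:
            raise ValueError("n_barcodes must be even (one pair per sample)")
        if self.n_barcodes // 2 < self.n_timepoints:
            raise ValueError("need one unique barcode pair per time point")
        if len(self.cluster_peak_times) != self.n_gene_clusters:
            raise ValueError("cluster_peak_times length must equal n_gene_clusters")
        t_end = self.t_start_hpf + self.n_timepoints - 1
        if not (self.t_start_hpf <= self.bifurcation_time <= t_end):
            raise ValueError("bifurcation_time outside the sampled time range")
        for name in ("n_timepoints", "n_cells_per_timepoint", "n_barcodes",
                     "n_genes", "n_gene_clusters"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def times_hpf(self) -> np.ndarray:
        return self.t_start_hpf + np.arange(self.n_timepoints, dtype=float)

    @classmethod
    def low_noise(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Low-noise preset: tight counts and near-synchronous embryos.

        Used for fixtures that probe the label-transfer and clustering
        machinery itself rather than its robustness to technical noise:
        hourly samples form tight, well-separated clusters (asynchrony
        sd 0.1 h keeps essentially every cell nearer its own hour than
        the adjacent one), so any transfer error is the machinery's.
        """
        params = dict(nb_dispersion=50.0, dropout_rate=0.02,
                      library_size_logsd=0.15, cell_age_jitter_h=0.1)
        params.update(overrides)
        return cls(seed=seed, **params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cluster_peak_times"] = list(d["cluster_peak_times"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cluster_peak_times" in d:
            d["cluster_peak_times"] = tuple(d["cluster_peak_times"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth covering every simulated cell and gene."""

    cells: pd.DataFrame    # cell_id, true_time_hpf, true_lineage, mosaic, captured
    genes: pd.DataFrame    # gene, true_cluster, true_maturity
    design: pd.DataFrame   # sample_id, barcode_id_1, barcode_id_2, time_hpf
    config: SimulationConfig = field(repr=False, default=None)


def _true_maturity_labels(cfg: SimulationConfig) -> list[str]:
    """Cluster maturity implied by peak times relative to the bifurcation.

    Immature: the earliest-peaking program (on in the founder population).
    Mature: peaks within the window before/at the bifurcation.  Terminal:
    peaks after the bifurcation (branch-restricted).  Others intermediate.
    """
    peaks = np.asarray(cfg.cluster_peak_times, dtype=float)
    labels = []
    earliest = int(np.argmin(peaks))
    for c, pk in enumerate(peaks):
        if c == earliest:
            labels.append("immature")
        elif cfg.bifurcation_time - cfg.maturity_window_h <= pk <= cfg.bifurcation_time:
            labels.append("mature")
        elif pk > cfg.bifurcation_time:
            labels.append("terminal")
        else:
            labels.append("intermediate")
    return labels


def simulate_timeseries(
    config: SimulationConfig,
) -> tuple[ad.AnnData, ad.AnnData, SyntheticTruth]:
    """Simulate the barcoded time series.

    Returns (expression AnnData cells x genes, barcode AnnData cells x
    barcodes, truth).  Counts are non-negative integers; identical seeds
    yield identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    times = cfg.times_hpf
    n_cells = cfg.n_timepoints * cfg.n_cells_per_timepoint

    cell_time = np.repeat(times, cfg.n_cells_per_timepoint)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    # embryos within a sample are asynchronous by a fraction of an hour;
    # this continuous "age" drives expression, the sample hour is the label
    age = cell_time + rng.normal(0.0, cfg.cell_age_jitter_h, size=n_cells)

    # lineage: founder before the bifurcation, then a 50/50 branch split
    post = age >= cfg.bifurcation_time
    lineage = np.where(post, rng.choice(["branchA", "branchB"], size=n_cells), "founder")

    # gene programs: Gaussian bumps; the two latest-peaking post-bifurcation
    # clusters (when present) are branch-restricted
    genes_per_cluster = np.full(cfg.n_gene_clusters, cfg.n_genes // cfg.n_gene_clusters)
    genes_per_cluster[: cfg.n_genes % cfg.n_gene_clusters] += 1
    gene_cluster = np.repeat(np.arange(cfg.n_gene_clusters), genes_per_cluster)
    peaks = np.asarray(cfg.cluster_peak_times, dtype=float)
    maturity = _true_maturity_labels(cfg)
    terminal = [c for c in range(cfg.n_gene_clusters) if maturity[c] == "terminal"]
    branch_of_cluster = {}
    for i, c in enumerate(terminal):
        branch_of_cluster[c] = "branchA" if i % 2 == 0 else "branchB"

    bump = np.exp(
        -((age[:, None] - peaks[gene_cluster][None, :]) ** 2)
        / (2 * cfg.bump_width_h**2)
    )  # cells x genes
    # founder cells prime both branch programs; after the split, the other
    # branch's transcripts decay exponentially (no discontinuity at the
    # bifurcation, mirroring transcript turnover)
    branch_mult = np.ones((n_cells, cfg.n_genes))
    shutdown = np.exp(-np.maximum(0.0, age - cfg.bifurcation_time) / cfg.branch_decay_h)
    for c, br in branch_of_cluster.items():
        cols = gene_cluster == c
        off = post & (lineage != br)
        branch_mult[np.ix_(off, cols)] = shutdown[off, None]

    depth = rng.lognormal(mean=0.0, sigma=cfg.library_size_logsd, size=n_cells)
    mu = depth[:, None] * (cfg.baseline_expression + cfg.program_amplitude * bump * branch_mult)

    # negative binomial via gamma-Poisson; dispersion theta: var = mu + mu^2/theta
    lam = rng.gamma(shape=cfg.nb_dispersion, scale=mu / cfg.nb_dispersion)
    counts = rng.poisson(lam)
    if cfg.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= cfg.dropout_rate

    gene_ids = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    expr = ad.AnnData(X=counts.astype(np.int64))
    expr.obs_names = cell_ids
    expr.var_names = gene_ids
    expr.obs["true_time_hpf"] = cell_time
    expr.obs["true_age_hpf"] = age
    expr.obs["true_lineage"] = lineage

    # ---- sample barcodes -------------------------------------------------
    bc_ids = [f"SBC{i:02d}" for i in range(cfg.n_barcodes)]
    design = pd.DataFrame({
        "sample_id": [f"T{int(t):02d}" for t in times],
        "barcode_id_1": [bc_ids[2 * i] for i in range(cfg.n_timepoints)],
        "barcode_id_2": [bc_ids[2 * i + 1] for i in range(cfg.n_timepoints)],
        "time_hpf": times,
    })
    mosaic = rng.random(n_cells) < cfg.mosaic_fraction
    captured = (~mosaic) & (rng.random(n_cells) < cfg.barcode_capture_rate)
    factor = rng.lognormal(mean=0.0, sigma=cfg.barcode_factor_logsd, size=n_cells)

    bc_counts = rng.poisson(cfg.barcode_lambda_bg, size=(n_cells, cfg.n_barcodes))
    sample_idx = np.repeat(np.arange(cfg.n_timepoints), cfg.n_cells_per_timepoint)
    lam_pair = cfg.barcode_lambda_high * factor
    # capture is defined as yielding nonzero designed-pair counts, so the
    # captured cells' signal is zero-truncated Poisson (at the default
    # lambda the truncation correction is ~e-20, numerically invisible)
    signal = rng.poisson(np.repeat(lam_pair[:, None], 2, axis=1))
    zero = signal == 0
    while zero.any():
        signal[zero] = rng.poisson(np.repeat(lam_pair[:, None], 2, axis=1)[zero])
        zero = signal == 0
    for s in range(cfg.n_timepoints):
        sel = (sample_idx == s) & captured
        for j, col in enumerate((2 * s, 2 * s + 1)):
            bc_counts[sel, col] += signal[sel, j]

    bcs = ad.AnnData(X=bc_counts.astype(np.int64))
    bcs.obs_names = cell_ids
    bcs.var_names = bc_ids

    truth = SyntheticTruth(
        cells=pd.DataFrame({
            "cell_id": cell_ids,
            "true_time_hpf": cell_time,
            "true_age_hpf": age,
            "true_lineage": lineage,
            "true_sample": [design["sample_id"].iloc[s] for s in sample_idx],
            "mosaic": mosaic,
            "captured": captured,
        }).set_index("cell_id"),
        genes=pd.DataFrame({
            "gene": gene_ids,
            "true_cluster": gene_cluster,
            "true_maturity": [maturity[c] for c in gene_cluster],
        }).set_index("gene"),
        design=design,
        config=cfg,
    )
    return expr, bcs, truth


def simulate_screen_counts(
    conditions: Sequence[dict],
    n_per_condition: int,
    seed: int = 0,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Multinomial phenotype counts per screen condition.

    ``conditions`` is a list of {"name": str, "category_probabilities":
    sequence summing to 1}.  Returns a long table (condition, category,
    count) whose per-condition totals equal ``n_per_condition``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        p = np.asarray(cond["category_probabilities"], dtype=float)
        if np.any(p < 0):
            raise ValueError(f"negative probability in condition {cond['name']!r}")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"probabilities for {cond['name']!r} must sum to 1")
        cats = categories or [f"cat{i}" for i in range(len(p))]
        counts = rng.multinomial(n_per_condition, p)
        for cat, k in zip(cats, counts):
            rows.append({"condition": cond["name"], "category": cat, "count": int(k)})
    return pd.DataFrame(rows)


def _rotate_toward(v: np.ndarray, angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vector v by a fixed angle in a random azimuthal direction."""
    if angle_rad == 0:
        return v
    # orthonormal basis around v
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, v)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    phi = rng.uniform(0, 2 * np.pi)
    return np.cos(angle_rad) * v + np.sin(angle_rad) * (np.cos(phi) * e1 + np.sin(phi) * e2)


def simulate_division_geometry(
    n_sets: int,
    angle_noise_deg: float = 0.0,
    asymmetry_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centroid/volume tables for division-geometry statistics.

    Each set (half-embryo) holds two sister cells divided along a planted
    axis — alternately the mediolateral (x) and anteroposterior (y)
    reference direction, perturbed by ``angle_noise_deg`` — plus two
    neighbor cells off-axis.  Sister volumes realize ``asymmetry_ratio``
    (smaller/larger).  Returns (centroid table, truth table).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 0 < asymmetry_ratio <= 1:
        raise ValueError("asymmetry_ratio must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    ml = np.array([1.0, 0.0, 0.0])
    ap = np.array([0.0, 1.0, 0.0])
    rows, truth = [], []
    for s in range(n_sets):
        planted = "mediolateral" if s % 2 == 0 else "anteroposterior"
        base_axis = ml if planted == "mediolateral" else ap
        axis = _rotate_toward(base_axis, np.deg2rad(angle_noise_deg), rng)
        center = rng.uniform(-50, 50, size=3)
        sep = 5.0
        p1 = center - 0.5 * sep * axis
        p2 = center + 0.5 * sep * axis
        # off-axis neighbors so triplet statistics are non-degenerate
        n1 = center + 4.0 * np.array([0.0, 0.0, 1.0]) + rng.normal(0, 0.2, 3)
        n2 = center + 4.0 * np.cross(axis, [0.0, 0.0, 1.0]) + rng.normal(0, 0.2, 3)
        v_large = 100.0
        v_small = v_large * asymmetry_ratio
        for label, p, vol in [("sister1", p1, v_large), ("sister2", p2, v_small),
                              ("neighbor1", n1, 80.0), ("neighbor2", n2, 80.0)]:
            rows.append({"embryo_id": f"emb{s:03d}", "cell_label": label,
                         "x": p[0], "y": p[1], "z": p[2], "volume": vol})
        truth.append({"embryo_id": f"emb{s:03d}", "axis_x": axis[0],
                      "axis_y": axis[1], "axis_z": axis[2],
                      "planted_orientation": planted,
                      "asymmetry_ratio": asymmetry_ratio})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_regulatory_fixture(
    n_genes: int,
    n_sites: int,
    n_enriched_motifs: int,
    seed: int = 0,
    n_motifs: int = 15,
    target_fraction: float = 0.25,
    enriched_site_prob: float = 0.8,
    inside_gene_bodies: bool = False,
) -> dict:
    """Toy regulatory landscape: gene models, motif sites, DA table.

    One artificial chromosome carries ``n_genes`` alternating-strand genes
    (2 kb bodies, 20 kb spacing; overlapping spans cannot occur at this
    spacing but are permitted by the annotation logic).  ``n_sites`` motif
    sites (10 bp) are scattered near genes — or strictly inside gene
    bodies when ``inside_gene_bodies`` — and a differential-accessibility
    contrast marks ~``target_fraction`` of sites as the target set.  The
    first ``n_enriched_motifs`` motif IDs are planted preferentially in
    target sites; with zero planted motifs, motif identity is independent
    of target membership and enrichment p-values are null-uniform.

    Returns dict with gene_models, sites (BED-like frame), da_table,
    rule (MotifSetRule selecting the target set), and truth.
    """
    if min(n_genes, n_sites) < 1 or n_enriched_motifs < 0:
        raise ValueError("counts must be >= 1 (n_enriched_motifs >= 0)")
    if n_enriched_motifs > n_motifs:
        raise ValueError("n_enriched_motifs cannot exceed n_motifs")
    rng = np.random.default_rng(seed)
    chrom = "chrS1"
    spacing, body = 20_000, 2_000
    genes = [
        GeneModel(f"g{i:04d}", chrom, 12_000 + i * spacing,
                  12_000 + i * spacing + body, "+" if i % 2 == 0 else "-")
        for i in range(n_genes)
    ]
    chrom_len = 12_000 + n_genes * spacing + 12_000

    motif_ids = [f"M{m:02d}" for m in range(n_motifs)]
    enriched = motif_ids[:n_enriched_motifs]
    is_target = rng.random(n_sites) < target_fraction
    starts = np.empty(n_sites, dtype=int)
    if inside_gene_bodies:
        gi = rng.integers(0, n_genes, size=n_sites)
        for i in range(n_sites):
            g = genes[gi[i]]
            starts[i] = rng.integers(g.start, g.end - 10)
    else:
        starts = rng.integers(0, chrom_len - 10, size=n_sites)
    motif_choice = []
    for i in range(n_sites):
        if enriched and is_target[i] and rng.random() < enriched_site_prob:
            motif_choice.append(enriched[int(rng.integers(0, len(enriched)))])
        else:
            motif_choice.append(motif_ids[int(rng.integers(0, n_motifs))])
    sites = pd.DataFrame({
        "site_id": [f"site{i:04d}" for i in range(n_sites)],
        "chrom": chrom,
        "start": starts,
        "end": starts + 10,
        "motif_id": motif_choice,
        "strand": ".",
    })
    lfc = np.where(is_target, rng.normal(1.5, 0.2, n_sites), rng.normal(0.0, 0.3, n_sites))
    fdr = np.where(is_target, rng.uniform(0.001, 0.05, n_sites),
                   rng.uniform(0.2, 0.95, n_sites))
    da = pd.DataFrame({
        "region_id": sites["site_id"],
        "contrast": "condition_vs_control",
        "log2fc": lfc,
        "fdr": fdr,
    })
    from .motifs import MotifSetRule

    rule = MotifSetRule("target_open", (("condition_vs_control", ">", 1.0),))
    return {
        "gene_models": genes,
        "sites": sites,
        "da_table": da,
        "rule": rule,
        "truth": {
            "enriched_motifs": enriched,
            "target_sites": set(sites.loc[is_target, "site_id"]),
        },
    }
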