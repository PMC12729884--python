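"""Synthetic single-cell and bulk cohorts with planted oxidative-stress structure.

The single-cell generator emulates the statistical skeleton of a multi-donor
post-infarction atlas: negative-binomial counts with gene-wise dispersion,
donor-level log-scale batch effects, a continuous per-cell latent
oxidative-stress program acting multiplicatively on a designated gene
program, mito%/library-size covariates, and summed-parent doublets.  The
bulk generator emulates the external validation cohort: 120 samples in 6
batches at 58.3% case prevalence with a handful of planted marker genes.

Every draw comes from one seeded ``numpy.random.Generator`` per call, so a
config + seed pair is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .exceptions import InvalidConfigError
from .genesets import GeneSetCollection, default_oxidative_stress_sets

CELL_METADATA_COLUMNS = (
    "donor", "sample", "condition", "percent_mt", "n_count", "n_feature", "cell_type",
)

DEFAULT_CELLTYPE_PROPS = {
    "Cardiomyocyte": 0.43,
    "Fibroblast": 0.20,
    "Endothelial": 0.13,
    "Other": 0.24,
}


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


@dataclass
class SCSimConfig:
    """Parameters of the single-cell simulator.

    ``stress_effect`` is the log2 fold-change applied to every stress-program
    gene per unit of the per-cell latent stress; ``stress_latent_sd`` is the
    log-scale dispersion of that (lognormal, hence right-skewed) latent.
    ``biphasic=True`` replaces the i.i.d. latent with a U-shaped function of
    a uniform latent time, emulating a stress trajectory that first relaxes
    and then rises toward a high-stress endpoint.
    """

    n_cells: int = 5000
    n_genes: int = 2000
    n_donors: int = 20
    n_samples: int = 29
    condition_split: float = 0.7
    celltype_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_PROPS)
    )
    stress_genes: list[str] | None = None
    stress_effect: float = 1.0
    stress_latent_sd: float = 0.5
    diffuse_frac: float = 0.30
    diffuse_sd: float = 0.5
    plasticity_link: float = 0.0
    mito_mean: float = 10.0
    mito_sd: float = 5.0
    doublet_frac: float = 0.0061
    batch_sd: float = 0.15
    depth_sd: float = 0.3
    biphasic: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "n_donors", "n_samples"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in ("condition_split", "doublet_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0,1], got {v}")
        total = sum(self.celltype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"celltype_props must sum to 1 (got {total:.6g})"
            )
        if self.mito_mean <= 0 or self.mito_sd <= 0:
            raise InvalidConfigError("mito_mean and mito_sd must be positive")


@dataclass
class SyntheticSCDataset:
    """Generated cells plus the ground truth that produced them."""

    adata: AnnData
    latent_stress: np.ndarray
    true_stratum: np.ndarray
    true_doublet: np.ndarray
    latent_time: np.ndarray | None
    config: SCSimConfig

    @property
    def matrix(self) -> AnnData:
        return self.adata


def _latent_stress(rng: np.random.Generator, cfg: SCSimConfig):
    """Per-cell latent stress; returns (stress, latent_time-or-None)."""
    if cfg.biphasic:
        # U-shaped stress along a uniform latent time: dips near t=0.35,
        # rises sharply toward the t=1 endpoint.
        t = rng.uniform(0.0, 1.0, cfg.n_cells)
        stress = 0.3 + 2.5 * (t - 0.35) ** 2 / 0.4225
        stress = stress + rng.normal(0.0, 0.05, cfg.n_cells)
        return np.clip(stress, 0.0, None), t
    stress = rng.lognormal(mean=0.0, sigma=cfg.stress_latent_sd, size=cfg.n_cells)
    return stress, None


def _stratum_from_scores(scores: np.ndarray) -> np.ndarray:
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    out = np.full(scores.shape, "DTOX", dtype=object)
    out[scores < q1] = "LOX"
    out[scores > q3] = "HOX"
    return out.astype(str)


def generate_sc(config: SCSimConfig) -> SyntheticSCDataset:
    """Simulate a multi-donor single-cell count matrix.

    Counts are gamma-Poisson (negative binomial) with lognormal gene-wise
    baseline means and dispersions, a lognormal per-cell depth factor,
    N(0, batch_sd) donor-by-gene log-scale effects, and a
    ``2 ** (stress_effect * latent_stress)`` multiplier on stress-program
    genes.  Cells in case-condition samples carry a modestly amplified
    latent stress (x1.5), mirroring elevated oxidative stress in disease.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes
    genes = gene_universe(n_genes)

    # -- sample / donor / condition design ---------------------------------
    donors = np.array([f"D{i:02d}" for i in range(config.n_donors)])
    samples = np.array([f"S{i:02d}" for i in range(config.n_samples)])
    # every donor contributes at least one sample where possible; the
    # remaining samples are assigned uniformly at random
    sample_donor = np.empty(config.n_samples, dtype=object)
    head = min(config.n_donors, config.n_samples)
    sample_donor[:head] = donors[:head]
    if config.n_samples > head:
        sample_donor[head:] = rng.choice(donors, size=config.n_samples - head)
    n_case = int(round(config.condition_split * config.n_samples))
    case_samples = rng.choice(config.n_samples, size=n_case, replace=False)
    sample_condition = np.full(config.n_samples, "Normal", dtype=object)
    sample_condition[case_samples] = "AMI"

    cell_sample = rng.integers(0, config.n_samples, size=n_cells)
    cell_donor = sample_donor[cell_sample]
    cell_condition = sample_condition[cell_sample]

    types = list(config.celltype_props)
    props = np.array([config.celltype_props[t] for t in types])
    cell_type = rng.choice(types, size=n_cells, p=props)

    # -- latent stress ------------------------------------------------------
    stress, latent_time = _latent_stress(rng, config)
    stress = stress * np.where(cell_condition == "AMI", 1.5, 1.0)

    # -- gene program -------------------------------------------------------
    if config.stress_genes is None:
        n_prog = max(1, int(round(0.045 * n_genes)))
        prog_idx = rng.choice(n_genes, size=n_prog, replace=False)
    else:
        name_to_idx = {g: i for i, g in enumerate(genes)}
        missing = [g for g in config.stress_genes if g not in name_to_idx]
        if missing:
            raise InvalidConfigError(
                f"stress genes not in universe: {missing[:5]}..."
            )
        prog_idx = np.array([name_to_idx[g] for g in config.stress_genes])
    in_program = np.zeros(n_genes, dtype=bool)
    in_program[prog_idx] = True

    # trajectory program: genes varying linearly with latent time so the
    # biphasic mode yields a recoverable 1-D trajectory
    traj_idx = np.array([], dtype=int)
    if config.biphasic:
        free = np.where(~in_program)[0]
        traj_idx = rng.choice(free, size=min(100, free.size), replace=False)

    # -- negative-binomial counts ------------------------------------------
    base_mean = rng.lognormal(mean=np.log(0.4), sigma=1.0, size=n_genes)
    dispersion = rng.lognormal(mean=np.log(0.4), sigma=0.5, size=n_genes)
    batch_effect = rng.normal(0.0, config.batch_sd, size=(config.n_donors, n_genes))
    donor_index = {d: i for i, d in enumerate(donors)}
    cell_batch_rows = np.array([donor_index[d] for d in cell_donor])
    depth = rng.lognormal(mean=0.0, sigma=config.depth_sd, size=n_cells)

    log_mu = (
        np.log(base_mean)[None, :].astype(np.float32)
        + batch_effect[cell_batch_rows].astype(np.float32)
    )
    log_mu[:, in_program] += (
        np.log(2.0) * config.stress_effect * stress[:, None]
    ).astype(np.float32)
    # diffuse transcriptome-wide response: a broad fraction of genes reacts
    # weakly to the stress latent (random sign/magnitude), as a stress
    # response does in real cells; this gives the stress axis a realistic
    # share of the leading expression variance
    if config.diffuse_frac > 0 and config.diffuse_sd > 0:
        n_diffuse = int(round(config.diffuse_frac * n_genes))
        diffuse_idx = rng.choice(n_genes, size=n_diffuse, replace=False)
        beta = np.zeros(n_genes, dtype=np.float32)
        beta[diffuse_idx] = rng.normal(0.0, config.diffuse_sd, n_diffuse)
        log_mu += beta[None, :] * stress[:, None].astype(np.float32)
    if traj_idx.size:
        log_mu[:, traj_idx] += (
            np.log(2.0) * 1.5 * latent_time[:, None]
        ).astype(np.float32)
    if config.plasticity_link > 0:
        # per-cell transcriptional noise grows with latent stress, planting
        # a stress-driven plasticity gradient (cross-gene variance)
        noise_sd = (config.plasticity_link * stress).astype(np.float32)
        log_mu += rng.standard_normal(log_mu.shape, dtype=np.float32) * noise_sd[:, None]
    mu = np.exp(log_mu, dtype=np.float32)
    # library size is technical: rescale each cell's expected counts to its
    # depth factor times the baseline total, so biological state changes
    # composition rather than sequencing depth
    target = (depth * base_mean.sum()).astype(np.float32)
    mu *= (target / mu.sum(axis=1))[:, None]

    r = (1.0 / dispersion)[None, :].astype(np.float32)
    lam = rng.gamma(shape=np.broadcast_to(r, mu.shape), scale=mu / r)
    counts = rng.poisson(lam).astype(np.int32)
    del lam, mu, log_mu

    # -- doublets: replace a fraction of cells with summed parents ---------
    n_doublets = int(round(config.doublet_frac * n_cells))
    true_doublet = np.zeros(n_cells, dtype=bool)
    if n_doublets > 0:
        dbl = rng.choice(n_cells, size=n_doublets, replace=False)
        true_doublet[dbl] = True
        singlets = np.where(~true_doublet)[0]
        p1 = rng.choice(singlets, size=n_doublets)
        p2 = rng.choice(singlets, size=n_doublets)
        counts[dbl] = counts[p1] + counts[p2]

    # -- covariates and assembly -------------------------------------------
    shape = (config.mito_mean / config.mito_sd) ** 2
    scale = config.mito_sd**2 / config.mito_mean
    percent_mt = np.clip(rng.gamma(shape, scale, size=n_cells), 0.0, 97.0)

    X = sp.csr_matrix(counts)
    obs = pd.DataFrame(
        {
            "donor": pd.Categorical(cell_donor.astype(str)),
            "sample": pd.Categorical(samples[cell_sample].astype(str)),
            "condition": pd.Categorical(cell_condition.astype(str)),
            "percent_mt": percent_mt,
            "n_count": np.asarray(X.sum(axis=1)).ravel().astype(np.int64),
            "n_feature": X.getnnz(axis=1).astype(np.int64),
            "cell_type": pd.Categorical(cell_type.astype(str)),
            "latent_stress": stress,
            "true_doublet": true_doublet,
        },
        index=[f"C{i:06d}" for i in range(n_cells)],
    )
    true_stratum = _stratum_from_scores(stress)
    obs["true_stratum"] = pd.Categorical(true_stratum)
    if latent_time is not None:
        obs["latent_time"] = latent_time
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    adata.var["stress_program"] = in_program
    adata.uns["sim"] = {"seed": config.seed, "generator": "oxstrata.simulate"}
    return SyntheticSCDataset(
        adata=adata,
        latent_stress=stress,
        true_stratum=true_stratum,
        true_doublet=true_doublet,
        latent_time=latent_time,
        config=config,
    )


def default_sc_dataset(
    seed: int = 42,
    n_cells: int = 5000,
    n_genes: int = 2000,
    stress_effect: float = 1.0,
    biphasic: bool = False,
) -> tuple[SyntheticSCDataset, GeneSetCollection]:
    """The default cardiomyocyte study dataset plus its five gene sets.

    The stress program is the union of the five oxidative-stress sets
    (sizes 23/18/17/16/16 with a shared core), so single-method scores and
    the composite are recoverably driven by the latent stress.
    """
    universe = gene_universe(n_genes)
    sets = default_oxidative_stress_sets(universe, seed=seed)
    cfg = SCSimConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        celltype_props={"Cardiomyocyte": 1.0},
        stress_genes=sets.union(),
        stress_effect=stress_effect,
        biphasic=biphasic,
        seed=seed,
    )
    return generate_sc(cfg), sets


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Parameters of the bulk validation-cohort simulator.

    ``marker_effect`` is the standardized mean difference (case minus
    control, in units of the per-gene noise SD) planted on each marker.
    """

    n_samples: int = 120
    n_batches: int = 6
    case_prevalence: float = 0.5833
    n_genes: int = 505
    planted_markers: list[str] | None = None
    marker_effect: float = 1.5
    batch_shift_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_batches <= 0:
            raise InvalidConfigError("dimensions must be positive")
        if self.n_batches > self.n_samples:
            raise InvalidConfigError("n_batches must not exceed n_samples")
        if not 0 < self.case_prevalence < 1:
            raise InvalidConfigError("case_prevalence must be in (0,1)")


@dataclass
class SyntheticBulkCohort:
    """Bulk expression with batch/label design and planted-marker truth."""

    expr: pd.DataFrame          # samples x genes
    batch: pd.Series            # per-sample batch id (1..n_batches)
    label: pd.Series            # "case" / "control"
    truth: dict[str, float]     # marker gene -> planted standardized effect

    @property
    def y(self) -> np.ndarray:
        return (self.label.to_numpy() == "case").astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat(
            [self.batch.rename("batch"), self.label.rename("label"), self.expr],
            axis=1,
        )
        df.index.name = "sample"
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SyntheticBulkCohort":
        df = pd.read_csv(path, index_col="sample")
        batch = df.pop("batch").astype(int)
        label = df.pop("label").astype(str)
        return cls(expr=df.astype(float), batch=batch, label=label, truth={})


def generate_bulk(config: BulkSimConfig) -> SyntheticBulkCohort:
    """Simulate the bulk cohort: baseline + batch shift + marker effect + noise.

    The case count is exactly ``round(prevalence * n_samples)`` (70 of 120 at
    the default 58.33% prevalence); batches are assigned round-robin so every
    id in 1..n_batches is used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config.n_genes)
    if config.planted_markers is None:
        markers = genes[: 5] if config.n_genes >= 5 else genes[:1]
    else:
        missing = [g for g in config.planted_markers if g not in set(genes)]
        if missing:
            raise InvalidConfigError(f"planted markers not in universe: {missing}")
        markers = list(config.planted_markers)

    n_case = int(round(config.case_prevalence * config.n_samples))
    y = np.zeros(config.n_samples, dtype=int)
    y[rng.choice(config.n_samples, size=n_case, replace=False)] = 1
    batch = (np.arange(config.n_samples) % config.n_batches) + 1
    batch = rng.permutation(batch)

    baseline = rng.normal(8.0, 2.0, size=config.n_genes)
    batch_shift = rng.normal(
        0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes)
    )
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_samples, config.n_genes))
    expr = baseline[None, :] + batch_shift[batch - 1] + noise
    marker_idx = [genes.index(m) for m in markers]
    expr[:, marker_idx] += (
        config.marker_effect * config.noise_sd * y[:, None]
    )

    sample_ids = [f"B{i:03d}" for i in range(config.n_samples)]
    return SyntheticBulkCohort(
        expr=pd.DataFrame(expr, index=sample_ids, columns=genes),
        batch=pd.Series(batch, index=sample_ids, name="batch"),
        label=pd.Series(
            np.where(y == 1, "case", "control"), index=sample_ids, name="label"
        ),
        truth={m: config.marker_effect for m in markers},
    )


# ---------------------------------------------------------------------------
# on-disk round trip (MTX + TSV sidecars)
# ---------------------------------------------------------------------------

def write_sc_dataset(adata: AnnData, outdir: str | Path) -> None:
    """Write genes x cells Matrix Market counts with TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    cols = [c for c in adata.obs.columns if c in CELL_METADATA_COLUMNS or c in (
        "latent_stress", "true_doublet", "true_stratum", "latent_time")]
    obs = adata.obs[cols].copy()
    obs.index.name = "cell"
    obs.to_csv(outdir / "cells.tsv", sep="\t")


def read_sc_dataset(indir: str | Path) -> AnnData:
    """Read a dataset written by :func:`write_sc_dataset`."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx"))).T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].astype(str)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col="cell")
    missing = [c for c in CELL_METADATA_COLUMNS if c not in obs.columns]
    if missing:
        warnings.warn(f"cell metadata missing columns: {missing}")
    return AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.to_numpy()))
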