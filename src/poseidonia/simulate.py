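"""Synthetic-data generators for every input the pipeline consumes.

Each generator is deterministic for a fixed seed and returns its ground-truth
parameters alongside the data, so parameter-recovery tests can compare
estimates against what was actually planted.

The negative-binomial parameterisation used throughout the package is
mean/dispersion with ``Var = mu + alpha * mu**2`` — the ``alpha`` that the
abundance models optimise by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .spectral import AlignedProteinSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# residues planted at the two diagnostic alignment columns, per pR clade
TUNING_RESIDUE = {"SP": "M", "DP": "Q"}  # column 315: green vs blue tuning
DONOR_RESIDUE = {"SP": "K", "DP": "E"}  # column 318: proton donor


@dataclass(frozen=True)
class TreeSimSpec:
    """Parameters for the random rooted-tree generator.

    rate_heterogeneity is the gamma shape of the per-edge rate multipliers;
    small values give strong branch-length variation among lineages.
    """

    n_leaves: int
    rate_heterogeneity: float = 1.0
    seed: int = 0
    base_branch_length: float = 0.1

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be at least 2")
        if self.rate_heterogeneity <= 0:
            raise ValueError("rate_heterogeneity must be positive")


@dataclass(frozen=True)
class MarkerSimSpec:
    """Parameters for the single-copy-marker copy-count generator."""

    n_genomes: int
    marker_ids: tuple[str, ...]
    true_completeness: tuple[float, ...]
    true_contamination: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("marker_ids must be non-empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        if len(self.true_completeness) != self.n_genomes:
            raise ValueError("true_completeness must have one entry per genome")
        if len(self.true_contamination) != self.n_genomes:
            raise ValueError("true_contamination must have one entry per genome")
        for c in self.true_completeness:
            if not 0.0 <= c <= 1.0:
                raise ValueError("completeness fractions must lie in [0, 1]")
        for k in self.true_contamination:
            if not 0.0 <= k <= 1.0:
                raise ValueError("contamination fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CountSimSpec:
    """Parameters for the negative-binomial clade-abundance generator.

    ``coefficients`` maps each clade to its per-covariate effect vector on
    the log scale; ``covariates`` is the per-sample design (samples × p).
    A seasonal sinusoid with period 12 (months) and the given amplitude is
    added to the linear predictor when ``seasonal_amplitude > 0``, using the
    covariate column named ``month`` (or sample index if absent).
    """

    n_samples: int
    n_clades: int
    coefficients: Mapping[str, Sequence[float]]
    dispersion_alpha: float
    covariates: pd.DataFrame | None = None
    seasonal_amplitude: float = 0.0
    baseline_log_mean: float = 4.0
    library_size_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_alpha <= 0:
            raise ValueError("dispersion_alpha must be positive")
        if len(self.coefficients) != self.n_clades:
            raise ValueError("coefficients must have one vector per clade")


@dataclass
class MarkerTableSim:
    """A simulated marker table plus the estimator values it should yield.

    ``expected_completeness`` / ``expected_contamination`` are the analytic
    expectations of the count-based estimators under the generative model
    (own copy ~ Bern(c); independent contaminant copy ~ Bern(k)):
    E[completeness] = 1-(1-c)(1-k), E[contamination] = c*k. Recovery tests
    compare against these, not against the raw parameters.
    """

    table: pd.DataFrame
    true_completeness: pd.Series
    true_contamination: pd.Series
    expected_completeness: pd.Series
    expected_contamination: pd.Series


@dataclass
class CountsSim:
    """Simulated clade × sample counts with full generative ground truth."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    library_multipliers: pd.Series
    true_mean: pd.DataFrame
    true_coefficients: dict[str, np.ndarray]
    dispersion_alpha: float


def simulate_tree(spec: TreeSimSpec) -> dendropy.Tree:
    """Generate a rooted binary tree by uniform random joins.

    Branch lengths are exponential draws (mean ``base_branch_length``)
    scaled by per-edge gamma multipliers with shape ``rate_heterogeneity``
    and mean 1, giving controllable among-lineage rate variation.
    """
    rng = np.random.default_rng(spec.seed)
    tns = dendropy.TaxonNamespace()
    pool: list[dendropy.Node] = []
    for i in range(spec.n_leaves):
        node = dendropy.Node()
        node.taxon = tns.new_taxon(f"G{i + 1:04d}")
        pool.append(node)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        right = pool.pop(int(j))
        left = pool.pop(int(i))
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        pool.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = pool[0]
    tree.is_rooted = True
    h = spec.rate_heterogeneity
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        base = rng.exponential(spec.base_branch_length)
        rate = rng.gamma(shape=h, scale=1.0 / h)
        node.edge.length = max(base * rate, 1e-12)
    return tree


def simulate_marker_table(
    spec: MarkerSimSpec, absent_markers: Sequence[str] = ()
) -> MarkerTableSim:
    """Generate a genome × marker copy-count table.

    Each genome's own copy of a marker is present with probability
    ``true_completeness``; an extra contaminant copy is added independently
    with probability ``true_contamination``. Markers in ``absent_markers``
    are forced to zero in every genome (emulating markers absent from the
    whole lineage, which marker-set refinement should remove).
    """
    unknown = set(absent_markers) - set(spec.marker_ids)
    if unknown:
        raise ValueError(f"absent_markers not in marker_ids: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    genomes = [f"MAG{i + 1:04d}" for i in range(spec.n_genomes)]
    comp = np.asarray(spec.true_completeness)[:, None]
    cont = np.asarray(spec.true_contamination)[:, None]
    m = len(spec.marker_ids)
    own = rng.random((spec.n_genomes, m)) < comp
    extra = rng.random((spec.n_genomes, m)) < cont
    counts = own.astype(int) + extra.astype(int)
    table = pd.DataFrame(counts, index=genomes, columns=list(spec.marker_ids))
    if absent_markers:
        table.loc[:, list(absent_markers)] = 0
    # expectations of the count-based estimators, valid once the forced-absent
    # markers have been removed from the marker set by refinement
    c = comp.ravel()
    k = cont.ravel()
    exp_comp = pd.Series(1 - (1 - c) * (1 - k), index=genomes)
    exp_cont = pd.Series(c * k, index=genomes)
    return MarkerTableSim(
        table=table,
        true_completeness=pd.Series(c, index=genomes),
        true_contamination=pd.Series(k, index=genomes),
        expected_completeness=exp_comp,
        expected_contamination=exp_cont,
    )


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) draws via the gamma–Poisson mixture; Var = mu + alpha mu^2."""
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_counts(spec: CountSimSpec) -> CountsSim:
    """Generate clade × sample NB counts with known covariate effects.

    The expected count of clade c in sample s is
    ``exp(b0 + x_s · beta_c + A sin(2π month_s / 12)) * L_s`` where ``L_s``
    is a lognormal library-size multiplier stored as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    if spec.covariates is not None:
        if len(spec.covariates) != spec.n_samples:
            raise ValueError("covariates must have one row per sample")
        meta = spec.covariates.copy()
        meta.index = samples
    else:
        meta = pd.DataFrame(index=samples)
    numeric = meta.select_dtypes(include=[np.number])
    # the month column drives the seasonal sinusoid, not the linear design
    design = numeric.drop(columns=["month"], errors="ignore").to_numpy(dtype=float)
    if "month" in meta.columns:
        month = meta["month"].to_numpy(dtype=float)
    else:
        month = np.arange(spec.n_samples, dtype=float)
    seasonal = spec.seasonal_amplitude * np.sin(2.0 * np.pi * month / 12.0)
    lib = pd.Series(
        np.exp(rng.normal(0.0, spec.library_size_sd, size=spec.n_samples)),
        index=samples,
        name="library_multiplier",
    )
    clades = list(spec.coefficients)
    true_mu = np.empty((len(clades), spec.n_samples))
    coef_out: dict[str, np.ndarray] = {}
    for r, clade in enumerate(clades):
        beta = np.asarray(spec.coefficients[clade], dtype=float)
        coef_out[clade] = beta
        if design.shape[1] != beta.size:
            raise ValueError(
                f"clade {clade!r}: {beta.size} coefficients for "
                f"{design.shape[1]} numeric covariates"
            )
        eta = spec.baseline_log_mean + (design @ beta if beta.size else 0.0) + seasonal
        true_mu[r] = np.exp(eta) * lib.to_numpy()
    counts = _nb_draws(rng, true_mu, spec.dispersion_alpha)
    counts_df = pd.DataFrame(counts, index=clades, columns=samples)
    mu_df = pd.DataFrame(true_mu, index=clades, columns=samples)
    return CountsSim(
        counts=counts_df,
        metadata=meta,
        library_multipliers=lib,
        true_mean=mu_df,
        true_coefficients=coef_out,
        dispersion_alpha=spec.dispersion_alpha,
    )


def simulate_pr_alignment(
    n_seqs: int,
    class_labels: Sequence[str],
    seed: int = 0,
    width: int = 650,
    tuning_col: int = 315,
    donor_col: int = 318,
    conservation: float = 0.7,
    gap_positions: Mapping[int, Sequence[int]] | None = None,
) -> tuple[AlignedProteinSet, list[str]]:
    """Generate a fixed-width pR protein alignment with planted class columns.

    Column ``tuning_col`` (1-based) carries M for SP (green-tuned) and Q for
    DP (blue-tuned); ``donor_col`` carries K for SP and E for DP. Every other
    column has a random consensus residue that each sequence matches with
    probability ``conservation`` (substituting a uniform random residue
    otherwise), mimicking the conservation profile of a real protein
    alignment. ``gap_positions`` maps a sequence index (0-based) to 1-based
    columns to overwrite with gaps, for testing degenerate inputs. Returns
    the alignment and the labels used.
    """
    labels = list(class_labels)
    if len(labels) != n_seqs:
        raise ValueError("class_labels must have one entry per sequence")
    for lab in labels:
        if lab not in TUNING_RESIDUE:
            raise ValueError(f"unknown pR class label {lab!r}; expected SP or DP")
    if width < max(tuning_col, donor_col):
        raise ValueError("alignment width must cover the diagnostic columns")
    if not 0.0 <= conservation <= 1.0:
        raise ValueError("conservation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    consensus = aa[rng.integers(0, len(aa), size=width)]
    ids = [f"pR{i + 1:04d}" for i in range(n_seqs)]
    rows = []
    for i, lab in enumerate(labels):
        chars = consensus.copy()
        mutate = rng.random(width) >= conservation
        chars[mutate] = aa[rng.integers(0, len(aa), size=int(mutate.sum()))]
        chars[tuning_col - 1] = TUNING_RESIDUE[lab]
        chars[donor_col - 1] = DONOR_RESIDUE[lab]
        if gap_positions and i in gap_positions:
            for col in gap_positions[i]:
                chars[col - 1] = "-"
        rows.append("".join(chars))
    return AlignedProteinSet(ids=ids, sequences=rows), labels
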