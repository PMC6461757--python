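"""End-to-end orchestration: simulate or load inputs, run every stage,
write a reproducible result bundle.

The bundle contains TSV tables, a taxon-decorated newick tree and a JSON
run manifest recording the package version, seed and every threshold, so a
run can be re-executed identically from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__, abundance, io, quality, red, simulate, spectral

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and outputs of a full run.

    Unset thresholds fall back to the published defaults carried by the
    stage modules. With ``simulate=True`` every input is generated by the
    synthetic-data module instead of being read from disk.
    """

    out_dir: str = "poseidonia_out"
    seed: int = 0
    simulate: bool = False
    # input paths (ignored when simulating)
    tree_path: str | None = None
    taxonomy_path: str | None = None
    marker_table_path: str | None = None
    mag_manifest_path: str | None = None
    identity_matrix_path: str | None = None
    alignment_path: str | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    # thresholds (published defaults)
    screen_min_completeness: float = quality.SCREEN_MIN_COMPLETENESS
    screen_max_contamination: float = quality.SCREEN_MAX_CONTAMINATION
    dereplication_threshold: float = quality.DEREPLICATION_THRESHOLD
    bh_variable_threshold: float = abundance.BH_VARIABLE_THRESHOLD
    bh_coefficient_threshold: float = abundance.BH_COEFFICIENT_THRESHOLD
    red_half_width: float = red.DEFAULT_HALF_WIDTH
    gam_df_min: int = abundance.GAM_DF_RANGE[0]
    gam_df_max: int = abundance.GAM_DF_RANGE[1]
    pos_tuning: int = spectral.TUNING_COLUMN
    pos_donor: int = spectral.DONOR_COLUMN
    min_similarity: float = 0.30
    termini: tuple[int, int] = (113, 585)
    # simulation sizes (used with simulate=True)
    sim_n_genomes: int = 40
    sim_n_markers: int = 120
    sim_n_samples: int = 24
    sim_n_clades: int = 8

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "termini" in data:
            data["termini"] = tuple(data["termini"])
        return cls(**data)

    def validate_thresholds(self) -> None:
        for name, value, lo, hi in [
            ("screen_min_completeness", self.screen_min_completeness, 0, 100),
            ("screen_max_contamination", self.screen_max_contamination, 0, 100),
            ("dereplication_threshold", self.dereplication_threshold, 0, 100),
            ("bh_variable_threshold", self.bh_variable_threshold, 0, 1),
            ("bh_coefficient_threshold", self.bh_coefficient_threshold, 0, 1),
            ("red_half_width", self.red_half_width, 0, 1),
            ("min_similarity", self.min_similarity, 0, 1),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if not 3 <= self.gam_df_min <= self.gam_df_max:
            raise ValueError("require 3 <= gam_df_min <= gam_df_max")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Report-only validation of the configured inputs; never mutates them."""
    report: list[str] = []
    if config.simulate:
        return report
    for name in (
        "tree_path",
        "taxonomy_path",
        "marker_table_path",
        "counts_path",
        "metadata_path",
        "alignment_path",
    ):
        path = getattr(config, name)
        if path and not Path(path).exists():
            report.append(f"{name}: file not found: {path}")
    tree_path = config.tree_path
    if tree_path and Path(tree_path).exists():
        try:
            tree = io.read_tree(tree_path)
            io.ensure_rooted(tree)
        except io.UnrootedTreeError as exc:
            report.append(f"tree_path: {exc} (a rooted tree or --outgroup is required)")
        except Exception as exc:  # noqa: BLE001
            report.append(f"tree_path: unreadable newick: {exc}")
    if config.alignment_path and Path(config.alignment_path).exists():
        from Bio import SeqIO

        widths = {}
        for rec in SeqIO.parse(config.alignment_path, "fasta"):
            widths[rec.id] = len(rec.seq)
        if len(set(widths.values())) > 1:
            mode = pd.Series(list(widths.values())).mode()[0]
            bad = [sid for sid, w in widths.items() if w != mode]
            report.append(f"alignment_path: ragged alignment; offending sequences: {bad}")
    if config.counts_path and Path(config.counts_path).exists():
        counts = io.read_table(config.counts_path)
        if counts.isna().any().any():
            report.append("counts_path: table is ragged or contains missing values")
        if config.metadata_path and Path(config.metadata_path).exists():
            meta = io.read_table(config.metadata_path)
            missing = [s for s in counts.columns if s not in meta.index]
            if missing:
                report.append(f"metadata_path: samples without metadata: {missing[:5]}")
    return report


def _simulated_inputs(config: PipelineConfig):
    """Generate a coherent input bundle from the synthetic-data module."""
    seed = config.seed
    tree = simulate.simulate_tree(
        simulate.TreeSimSpec(n_leaves=config.sim_n_genomes, rate_heterogeneity=0.8, seed=seed)
    )
    leaves = sorted(l.taxon.label for l in tree.leaf_nodes())
    # paint a clade-true seed taxonomy: root children become families and a
    # frontier decomposition of each family becomes its genera
    taxonomy = {}
    fam_nodes = tree.seed_node.child_nodes()
    genus_counter = 0
    for fi, fam_node in enumerate(fam_nodes):
        fam = f"Family{'AB'[fi % 2]}{'' if fi < 2 else fi}"
        frontier = [fam_node]
        while len(frontier) < 3:
            frontier.sort(key=lambda n: -len(n.leaf_nodes()))
            head = frontier[0]
            if head.is_leaf():
                break
            frontier = head.child_nodes() + frontier[1:]
        for node in frontier:
            genus_counter += 1
            for leaf in node.leaf_nodes():
                taxonomy[leaf.taxon.label] = (
                    f"d__Archaea;o__OrderX;f__{fam};g__Genus{genus_counter}"
                )
    rng = np.random.default_rng(seed + 1)
    comp = rng.uniform(0.5, 1.0, config.sim_n_genomes)
    cont = rng.uniform(0.0, 0.08, config.sim_n_genomes)
    markers = tuple(f"MK{i + 1:04d}" for i in range(config.sim_n_markers))
    msim = simulate.simulate_marker_table(
        simulate.MarkerSimSpec(
            n_genomes=config.sim_n_genomes,
            marker_ids=markers,
            true_completeness=tuple(comp),
            true_contamination=tuple(cont),
            seed=seed + 2,
        ),
        absent_markers=markers[-5:],
    )
    msim.table.index = leaves[: config.sim_n_genomes]
    # identity matrix from patristic distances (monotone map, deterministic)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaves)
    ident = np.full((n, n), 100.0)
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i < j:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                ident[i, j] = ident[j, i] = 100.0 * float(np.exp(-d / 2.0))
    identity = pd.DataFrame(ident, index=leaves, columns=leaves)
    months = np.arange(config.sim_n_samples) % 12
    covars = pd.DataFrame(
        {
            "temperature": rng.normal(18, 4, config.sim_n_samples).round(2),
            "month": months,
        }
    )
    coefs = {f"clade{i + 1}": [float(rng.normal(0, 0.05))] for i in range(config.sim_n_clades)}
    csim = simulate.simulate_counts(
        simulate.CountSimSpec(
            n_samples=config.sim_n_samples,
            n_clades=config.sim_n_clades,
            coefficients=coefs,
            dispersion_alpha=0.3,
            covariates=covars,
            seasonal_amplitude=0.8,
            seed=seed + 3,
        )
    )
    aln, labels = simulate.simulate_pr_alignment(
        n_seqs=20,
        class_labels=["SP" if i % 2 == 0 else "DP" for i in range(20)],
        seed=seed + 4,
        tuning_col=config.pos_tuning,
        donor_col=config.pos_donor,
    )
    return tree, taxonomy, msim.table, identity, csim, aln


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle to ``out_dir``.

    Returns a summary dict (also written as ``manifest.json``). Any stage
    failure raises :class:`StageError` naming the stage.
    """
    config.validate_thresholds()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        tree, taxonomy, marker_table, identity, csim, aln = _simulated_inputs(config)
        counts, metadata = csim.counts, csim.metadata
    else:
        for name in ("tree_path", "taxonomy_path", "marker_table_path"):
            path = getattr(config, name)
            if not path or not Path(path).exists():
                raise StageError("inputs", f"missing input path for {name}: {path}")
        tree = io.read_tree(config.tree_path)
        taxonomy = io.read_seed_taxonomy(config.taxonomy_path)
        marker_table = io.read_table(config.marker_table_path)
        identity = (
            io.read_table(config.identity_matrix_path)
            if config.identity_matrix_path
            else None
        )
        aln = (
            spectral.AlignedProteinSet.from_fasta(config.alignment_path)
            if config.alignment_path
            else None
        )
        counts = io.read_table(config.counts_path) if config.counts_path else None
        metadata = io.read_table(config.metadata_path) if config.metadata_path else None

    manifest: dict = {
        "package": "poseidonia",
        "version": __version__,
        "seed": config.seed,
        "simulate": config.simulate,
        "thresholds": {
            "screen_min_completeness": config.screen_min_completeness,
            "screen_max_contamination": config.screen_max_contamination,
            "dereplication_threshold": config.dereplication_threshold,
            "bh_variable_threshold": config.bh_variable_threshold,
            "bh_coefficient_threshold": config.bh_coefficient_threshold,
            "red_half_width": config.red_half_width,
            "gam_df_range": [config.gam_df_min, config.gam_df_max],
            "pos_tuning": config.pos_tuning,
            "pos_donor": config.pos_donor,
            "min_similarity": config.min_similarity,
            "termini": list(config.termini),
        },
        "stages": {},
    }

    # --- quality ----------------------------------------------------------
    try:
        refined = quality.refine_marker_set(marker_table, list(marker_table.columns))
        estimates = quality.estimate_quality(marker_table, refined)
        records = [
            quality.MAGRecord(
                genome_id=g,
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
            )
            for g, row in estimates.iterrows()
        ]
        kept, excluded = quality.screen_mags(
            records, config.screen_min_completeness, config.screen_max_contamination
        )
        io.write_table(estimates.round(4), out / "quality_estimates.tsv")
        manifest["stages"]["quality"] = {
            "markers_in": int(marker_table.shape[1]),
            "markers_retained": len(refined),
            "genomes": len(records),
            "kept": len(kept),
            "excluded": len(excluded),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quality", str(exc)) from exc

    # --- dereplication ----------------------------------------------------
    try:
        if identity is not None:
            keep_ids = [r.genome_id for r in kept if r.genome_id in identity.index]
            sub = identity.loc[keep_ids, keep_ids]
            reps, clusters = quality.dereplicate(sub, kept, config.dereplication_threshold)
            pd.Series(
                {rep: ",".join(m) for rep, m in clusters.items()}, name="members"
            ).rename_axis("representative").to_frame().to_csv(
                out / "dereplication.tsv", sep="\t"
            )
            manifest["stages"]["dereplicate"] = {
                "input": len(keep_ids),
                "representatives": len(reps),
            }
    except Exception as exc:
        raise StageError("dereplicate", str(exc)) from exc

    # --- RED and rank normalisation ---------------------------------------
    try:
        annotation = red.compute_red(tree)
        windows = red.fit_rank_windows(annotation, taxonomy, half_width=config.red_half_width)
        assignments = red.normalise_taxonomy(annotation, taxonomy, windows)
        red.assignments_to_table(assignments).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        red.decorate_tree(tree, assignments)
        io.write_tree(tree, out / "decorated_tree.nwk")
        manifest["stages"]["red"] = {
            "windows": {r: [w.low, w.high] for r, w in windows.items()},
            "taxa": len(assignments),
            "split": sum(1 for a in assignments if a.status == "split_child"),
        }
    except Exception as exc:
        raise StageError("red", str(exc)) from exc

    # --- spectral tuning ---------------------------------------------------
    try:
        if aln is not None:
            filtered = spectral.filter_alignment(
                aln, config.min_similarity, config.termini[0], config.termini[1]
            )
            calls = spectral.classify_all(filtered, config.pos_tuning, config.pos_donor)
            calls.to_csv(out / "spectral_calls.tsv", sep="\t")
            manifest["stages"]["spectral"] = {
                "sequences": int(calls.shape[0]),
                "green_SP": int((calls["spectral_class"] == "green_SP").sum()),
                "blue_DP": int((calls["spectral_class"] == "blue_DP").sum()),
            }
    except Exception as exc:
        raise StageError("spectral", str(exc)) from exc

    # --- abundance statistics ----------------------------------------------
    try:
        if counts is not None and metadata is not None:
            counts = abundance.exclude_sparse_samples(counts)
            metadata = metadata.loc[counts.columns]
            factors, _ = abundance.scale_by_library_size(counts)
            dataset = abundance.AbundanceDataset(counts, metadata, size_factors=factors)
            fits = []
            variables = [v for v in metadata.columns if v != "month"]
            for clade in counts.index:
                for variable in variables:
                    fits.append(abundance.fit_nb_glm(dataset, clade, variable))
            screen = abundance.significance_screen(
                fits, config.bh_variable_threshold, config.bh_coefficient_threshold
            )
            screen.to_csv(out / "correlations.tsv", sep="\t", index=False)
            gam_rows = []
            if "month" in metadata.columns:
                tvals = np.arange(counts.shape[1], dtype=float)
                for clade in counts.index:
                    g = abundance.fit_nb_gam(
                        dataset.scaled_counts.loc[clade],
                        tvals,
                        df_range=(config.gam_df_min, config.gam_df_max),
                    )
                    gam_rows.append(
                        {
                            "clade": clade,
                            "spline_df": g.spline_df,
                            "alpha": round(g.alpha, 6),
                            "aic": round(g.aic, 4),
                            "significant_vs_baseline": g.significant_vs_baseline,
                        }
                    )
                pd.DataFrame(gam_rows).to_csv(out / "gam_fits.tsv", sep="\t", index=False)
            manifest["stages"]["abundance"] = {
                "glm_fits": len(fits),
                "significant": int(screen.shape[0]),
                "gam_fits": len(gam_rows),
            }
    except Exception as exc:
        raise StageError("abundance", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
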