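"""MAG quality estimation, screening, MIMAG rules, and dereplication.

Completeness and contamination are estimated from lineage-specific
single-copy marker counts using the single-marker approximation:
completeness is the fraction of markers present at least once, and
contamination the fraction of extra copies. Before estimation the marker
set is refined by removing markers absent from *every* genome in the
lineage, since such markers say nothing about the lineage and would only
depress completeness. Downstream rules implement the community MIMAG
high-quality-draft standard, a quality score of completeness minus four
times contamination for ranking candidate type material, and greedy
dereplication of near-identical genomes at an average-nucleotide-identity
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: marker genes absent from every genome of the Poseidoniales lineage and
#: therefore removed from its CheckM-style marker set before estimation
POSEIDONIALES_ABSENT_MARKERS = (
    "TIGR00537",
    "TIGR02237",
    "TIGR00422",
    "PF01287.15",
    "TIGR03677",
    "PF09249.6",
    "PF13685.1",
    "TIGR00162",
    "PF02649.9",
    "PF03684.8",
    "PF01849.13",
)

#: default screening thresholds: exclude below 20% completeness or above
#: 10% contamination (keep side is inclusive)
SCREEN_MIN_COMPLETENESS = 20.0
SCREEN_MAX_CONTAMINATION = 10.0

#: dereplication identity threshold (%, average nucleotide identity)
DEREPLICATION_THRESHOLD = 99.5

#: MIMAG high-quality-draft rules (completeness/contamination strict,
#: rRNA lengths and tRNA count inclusive)
MIMAG_MIN_COMPLETENESS = 90.0
MIMAG_MAX_CONTAMINATION = 5.0
MIMAG_RRNA_MIN_BP = {"16S": 1200, "23S": 1900, "5S": 100}
MIMAG_MIN_TRNAS = 18

#: additional assembly rules for type-material candidacy
TYPE_MAX_CONTIGS = 100
TYPE_MAX_AMBIGUOUS_BASES = 10  # strict: fewer than ten ambiguous bases


@dataclass
class MAGRecord:
    """Per-genome quality and assembly attributes."""

    genome_id: str
    completeness: float  # percent
    contamination: float  # percent
    n_contigs: int = 0
    n_ambiguous_bases: int = 0
    rrna_lengths: dict[str, int] = field(default_factory=dict)  # {16S,23S,5S} -> bp
    n_trnas: int = 0
    family: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.genome_id}: negative contamination")

    @property
    def quality_score(self) -> float:
        """Completeness minus four times contamination."""
        return self.completeness - 4.0 * self.contamination


@dataclass
class QualityDecision:
    genome_id: str
    passed_screen: bool
    is_mimag_hq: bool
    quality_score: float
    reasons: list[str] = field(default_factory=list)


def refine_marker_set(table: pd.DataFrame, full_set: Sequence[str]) -> list[str]:
    """Drop markers with zero copies in every genome of the lineage.

    ``table`` is a genome × marker copy-count matrix. Markers in
    ``full_set`` missing from the table are treated as all-zero. The result
    preserves the order of ``full_set``; refining twice is a no-op.
    """
    if not len(full_set):
        raise ValueError("full_set must be non-empty")
    if table.shape[0] == 0:
        raise ValueError("marker table covers no genomes")
    retained = []
    for marker in full_set:
        if marker in table.columns and (table[marker] > 0).any():
            retained.append(marker)
    if not retained:
        logger.warning("all %d markers absent from every genome", len(full_set))
    return retained


def estimate_quality(table: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    """Per-genome completeness and contamination (%) from marker counts.

    completeness = 100 · (#markers with copy ≥ 1) / |markers|;
    contamination = 100 · Σ max(copy − 1, 0) / |markers|. This is the
    single-marker approximation (marker lists with counts, not collocated
    marker sets).
    """
    markers = list(markers)
    if not markers:
        raise ValueError("empty marker list")
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise ValueError(f"markers not in table: {missing[:5]}")
    sub = table[markers].to_numpy()
    completeness = 100.0 * (sub >= 1).sum(axis=1) / len(markers)
    contamination = 100.0 * np.maximum(sub - 1, 0).sum(axis=1) / len(markers)
    return pd.DataFrame(
        {"completeness": completeness, "contamination": contamination},
        index=table.index,
    )


def screen_mags(
    records: Iterable[MAGRecord],
    min_completeness: float = SCREEN_MIN_COMPLETENESS,
    max_contamination: float = SCREEN_MAX_CONTAMINATION,
) -> tuple[list[MAGRecord], list[QualityDecision]]:
    """Partition MAGs into kept and excluded by quality thresholds.

    A genome is kept iff completeness ≥ min AND contamination ≤ max; the
    boundary lies on the keep side (exclusion is written as "< min" /
    "> max"). Excluded genomes carry the failed-rule names.
    """
    if not 0 <= min_completeness <= 100 or not 0 <= max_contamination <= 100:
        raise ValueError("thresholds must lie in [0, 100]")
    kept: list[MAGRecord] = []
    excluded: list[QualityDecision] = []
    for rec in records:
        reasons = []
        if rec.completeness < min_completeness:
            reasons.append("completeness")
        if rec.contamination > max_contamination:
            reasons.append("contamination")
        if reasons:
            excluded.append(
                QualityDecision(
                    genome_id=rec.genome_id,
                    passed_screen=False,
                    is_mimag_hq=False,
                    quality_score=rec.quality_score,
                    reasons=reasons,
                )
            )
        else:
            kept.append(rec)
    return kept, excluded


def mimag_high_quality(record: MAGRecord) -> tuple[bool, list[str]]:
    """MIMAG high-quality-draft check.

    Requires completeness strictly > 90%, contamination strictly < 5%,
    near-full-length rRNA genes (16S ≥ 1200 bp, 23S ≥ 1900 bp, 5S ≥ 100 bp)
    and at least 18 tRNAs. Missing rRNA entries count as length 0.
    """
    failed = []
    if not record.completeness > MIMAG_MIN_COMPLETENESS:
        failed.append("completeness")
    if not record.contamination < MIMAG_MAX_CONTAMINATION:
        failed.append("contamination")
    for gene, min_bp in MIMAG_RRNA_MIN_BP.items():
        if record.rrna_lengths.get(gene, 0) < min_bp:
            failed.append(gene)
    if record.n_trnas < MIMAG_MIN_TRNAS:
        failed.append("tRNAs")
    return (not failed), failed


def select_type_material(records: Iterable[MAGRecord]) -> dict[str, MAGRecord]:
    """Choose one candidate type-material genome per family.

    Candidates must be MIMAG high quality, have at most 100 contigs and
    fewer than ten ambiguous bases; the winner per family maximises the
    quality score (completeness − 4 × contamination), ties broken
    lexicographically by genome id. Families without a candidate are
    omitted with a warning.
    """
    candidates: dict[str, list[MAGRecord]] = {}
    families = set()
    for rec in records:
        families.add(rec.family)
        hq, _ = mimag_high_quality(rec)
        if (
            hq
            and rec.n_contigs <= TYPE_MAX_CONTIGS
            and rec.n_ambiguous_bases < TYPE_MAX_AMBIGUOUS_BASES
        ):
            candidates.setdefault(rec.family, []).append(rec)
    chosen: dict[str, MAGRecord] = {}
    for family in sorted(families):
        pool = candidates.get(family)
        if not pool:
            logger.warning("family %r has no type-material candidate", family)
            continue
        chosen[family] = max(pool, key=lambda r: (r.quality_score, _neg_id(r)))
    return chosen


def _neg_id(rec: MAGRecord):
    # invert lexicographic order so max() prefers the earlier id on ties
    return tuple(-ord(ch) for ch in rec.genome_id)


def dereplicate(
    identity_matrix: pd.DataFrame,
    records: Sequence[MAGRecord],
    threshold: float = DEREPLICATION_THRESHOLD,
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy dereplication at an identity threshold (%).

    Repeatedly takes the unassigned genome with the highest quality score
    (ties lexicographic by id) as a representative and assigns to it every
    unassigned genome with identity ≥ threshold. Returns the representative
    ids and the clusters; representatives are pairwise below the threshold
    and the result is invariant to input row order.
    """
    ids = list(identity_matrix.index)
    if list(identity_matrix.columns) != ids:
        raise ValueError("identity matrix rows and columns must match")
    mat = identity_matrix.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("identity matrix must be symmetric")
    scores = {r.genome_id: r.quality_score for r in records}
    missing = [g for g in ids if g not in scores]
    if missing:
        raise ValueError(f"no quality record for genomes: {missing[:5]}")
    remaining = set(ids)
    order = sorted(ids, key=lambda g: (-scores[g], g))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    pos = {g: i for i, g in enumerate(ids)}
    for g in order:
        if g not in remaining:
            continue
        members = [
            h for h in ids if h in remaining and mat[pos[g], pos[h]] >= threshold
        ]
        for h in members:
            remaining.discard(h)
        reps.append(g)
        clusters[g] = members
    return reps, clusters


def trait_prevalence(
    trait_table: pd.DataFrame, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Per-genus proportion of genomes carrying each trait.

    ``trait_table`` is genome × trait presence (bool or 0/1); ``taxonomy``
    maps every genome to its genus. Entries are carriers / genus size.
    """
    unassigned = [g for g in trait_table.index if g not in taxonomy]
    if unassigned:
        raise ValueError(f"genomes without genus assignment: {unassigned[:5]}")
    genus = pd.Series({g: taxonomy[g] for g in trait_table.index}, name="genus")
    return trait_table.astype(float).groupby(genus).mean()
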