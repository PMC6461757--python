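"""Proteorhodopsin spectral-tuning and proton-donor classification.

Proteorhodopsin (pR) absorption maxima in marine plankton are governed by a
single residue of the retinal pocket: a nonpolar methionine yields maximal
absorption at 525 nm (green light, the shallow-photic SP type) while a polar
glutamine shifts it to 490 nm (blue light, the deep-photic DP type). A
second conserved position distinguishes proton-pumping pRs (glutamate or
lysine donors) from photosensory ones (phenylalanine or serine). Both
positions are addressed as 1-based columns of the *unfiltered* protein
alignment; filtering keeps an index map so the original coordinates remain
addressable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GAP = "-"
ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX" + GAP)

#: default 1-based alignment columns of the diagnostic residues
TUNING_COLUMN = 315
DONOR_COLUMN = 318

#: absorption maxima (nm) implied by the tuning residue
GREEN_NM = 525
BLUE_NM = 490

SPECTRAL_BY_RESIDUE = {"M": ("green_SP", GREEN_NM), "Q": ("blue_DP", BLUE_NM)}
DONOR_BY_RESIDUE = {
    "E": "proton_pump_E",
    "K": "proton_pump_K",
    "F": "photosensor",
    "S": "photosensor",
}


@dataclass
class AlignedProteinSet:
    """A fixed-width protein alignment with original-column addressing.

    ``column_map`` maps 1-based columns of the original alignment to 0-based
    indices of the stored sequences; it is the identity for a fresh
    alignment and shrinks under filtering.
    """

    ids: list[str]
    sequences: list[str]
    column_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError("alignment is ragged: unequal sequence widths")
        if not self.column_map and self.sequences:
            self.column_map = {c + 1: c for c in range(len(self.sequences[0]))}

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def sequence(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def residue_at(self, seq_id: str, original_column: int) -> str | None:
        """Residue at a 1-based *original* column, or None if filtered out."""
        idx = self.column_map.get(original_column)
        if idx is None:
            return None
        return self.sequence(seq_id)[idx]

    @classmethod
    def from_fasta(cls, path) -> "AlignedProteinSet":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(ids=ids, sequences=seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class SpectralCall:
    """Per-sequence classification of spectral tuning and proton donor."""

    sequence_id: str
    residue_tuning: str | None
    residue_donor: str | None
    spectral_class: str  # green_SP | blue_DP | unknown
    absorption_max_nm: int | None  # 525 | 490 | None
    donor_class: str  # proton_pump_E | proton_pump_K | photosensor | unknown


def filter_alignment(
    aln: AlignedProteinSet,
    min_similarity: float = 0.30,
    start_col: int = 113,
    end_col: int = 585,
) -> AlignedProteinSet:
    """Trim termini and drop poorly conserved columns, keeping an index map.

    Columns outside ``[start_col, end_col]`` (1-based, inclusive, original
    coordinates) are removed, as are columns whose most frequent non-gap
    residue occurs in fewer than ``min_similarity`` of the sequences.
    Original column numbers remain addressable through ``column_map``.
    """
    if aln.n_sequences == 0:
        raise ValueError("cannot filter an empty alignment")
    end_col = min(end_col, max(aln.column_map))
    if not 1 <= start_col <= end_col:
        raise ValueError("require 1 <= start_col <= end_col <= alignment width")
    matrix = np.array([list(s) for s in aln.sequences])
    kept: list[int] = []
    for orig_col, idx in sorted(aln.column_map.items()):
        if not start_col <= orig_col <= end_col:
            continue
        column = matrix[:, idx]
        residues, counts = np.unique(column[column != GAP], return_counts=True)
        modal = counts.max() / aln.n_sequences if residues.size else 0.0
        if modal >= min_similarity:
            kept.append(orig_col)
    old_idx = [aln.column_map[c] for c in kept]
    new_seqs = ["".join(matrix[i, old_idx]) for i in range(aln.n_sequences)]
    return AlignedProteinSet(
        ids=list(aln.ids),
        sequences=new_seqs,
        column_map={c: j for j, c in enumerate(kept)},
    )


def classify_spectral(
    aln: AlignedProteinSet, seq_id: str, tuning_col: int = TUNING_COLUMN
) -> SpectralCall:
    """Call the spectral class of one sequence from its tuning residue.

    M → green-tuned SP (525 nm); Q → blue-tuned DP (490 nm); a gap, X or any
    other residue gives an ``unknown`` call with no absorption maximum. The
    donor field is filled in by :func:`classify_donor` semantics as well so a
    single call carries both classifications.
    """
    residue = aln.residue_at(seq_id, tuning_col)
    spectral_class, nm = SPECTRAL_BY_RESIDUE.get(residue, ("unknown", None))
    donor_res = aln.residue_at(seq_id, DONOR_COLUMN)
    donor = DONOR_BY_RESIDUE.get(donor_res, "unknown")
    return SpectralCall(
        sequence_id=seq_id,
        residue_tuning=residue,
        residue_donor=donor_res,
        spectral_class=spectral_class,
        absorption_max_nm=nm,
        donor_class=donor,
    )


def classify_donor(
    aln: AlignedProteinSet, seq_id: str, donor_col: int = DONOR_COLUMN
) -> str:
    """Call the proton-donor class from the donor-position residue.

    E and K mark light-driven proton pumps (with distinct donors); F or S
    mark photosensory rhodopsins; anything else — including gaps and X — is
    ``unknown``.
    """
    residue = aln.residue_at(seq_id, donor_col)
    return DONOR_BY_RESIDUE.get(residue, "unknown")


def classify_all(
    aln: AlignedProteinSet,
    tuning_col: int = TUNING_COLUMN,
    donor_col: int = DONOR_COLUMN,
) -> pd.DataFrame:
    """Tabulate spectral and donor calls for every sequence."""
    rows = []
    for sid in aln.ids:
        call = classify_spectral(aln, sid, tuning_col)
        rows.append(
            {
                "sequence_id": sid,
                "residue_tuning": call.residue_tuning,
                "residue_donor": call.residue_donor,
                "spectral_class": call.spectral_class,
                "absorption_max_nm": call.absorption_max_nm,
                "donor_class": classify_donor(aln, sid, donor_col),
            }
        )
    return pd.DataFrame(rows).set_index("sequence_id")


def class_by_depth(
    calls: Sequence[SpectralCall],
    depths: Mapping[str, float],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Fractions of green/blue/unknown calls within sampling-depth bins.

    ``depths`` maps sequence id to sampling depth in metres; ``bin_edges``
    must cover every depth (bins are left-inclusive, the last bin closed).
    Fractions in each occupied bin sum to 1.
    """
    edges = list(bin_edges)
    classes = {"green_SP": "green", "blue_DP": "blue", "unknown": "unknown"}
    records = []
    for call in calls:
        if call.sequence_id not in depths:
            raise ValueError(f"no depth for sequence {call.sequence_id!r}")
        d = depths[call.sequence_id]
        if not edges[0] <= d <= edges[-1]:
            raise ValueError(f"depth {d} m outside bins [{edges[0]}, {edges[-1]}]")
        records.append({"depth": d, "cls": classes[call.spectral_class]})
    df = pd.DataFrame(records)
    df["bin"] = pd.cut(df["depth"], bins=edges, include_lowest=True)
    table = (
        df.groupby("bin", observed=True)["cls"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for col in ("green", "blue", "unknown"):
        if col not in table:
            table[col] = 0.0
    return table[["green", "blue", "unknown"]]
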