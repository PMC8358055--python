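"""Aligned protein families: parsing, consensus profiles and Shannon entropy.

An aligned family (e.g. a Pfam full alignment) is the entry point of the
sequence-space stage.  Sequences are scored by compositional Shannon
entropy

    H = -sum_a p_a log2 p_a        (a over the 20 standard residues)

where ``p_a`` is the fraction of residue ``a`` among the non-gap positions
of the sequence.  Entropy therefore lies in [0, log2 20 ~ 4.32] bits.  A
sequence is called *ordered* when its entropy falls strictly below a
disorder threshold (2.9 bits by default) and *disordered* otherwise.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "MAX_ENTROPY_BITS",
    "DISORDER_THRESHOLD_BITS",
    "AlignedFamily",
    "ConsensusProfile",
    "read_alignment",
    "build_consensus",
    "sequence_entropy",
    "classify_order",
    "entropy_report",
]

logger = logging.getLogger(__name__)

#: The 20 standard residues in fixed alphabetical order (tie-break order).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical gap symbol; '.' and unknown residue codes are mapped onto it.
GAP = "-"

#: Non-standard one-letter codes folded into the gap state so the 20-state
#: composition model stays exact.
_UNKNOWN_CODES = set("BJZXUO*")

MAX_ENTROPY_BITS = float(np.log2(20.0))

#: Disorder threshold in bits: entropy >= threshold is classed disordered.
DISORDER_THRESHOLD_BITS = 2.9

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class AlignmentShapeError(ValueError):
    """Raised when rows of an alignment disagree in length or count."""


def _canonicalize(seq: str) -> str:
    """Upper-case, map '.'/'-' to the canonical gap and fold unknown codes."""
    out = []
    unknown_seen = set()
    for ch in seq.upper():
        if ch in (".", "-", "~"):
            out.append(GAP)
        elif ch in _AA_INDEX:
            out.append(ch)
        elif ch in _UNKNOWN_CODES:
            unknown_seen.add(ch)
            out.append(GAP)
        else:
            raise ValueError(f"unrecognized residue code {ch!r}")
    if unknown_seen:
        logger.warning(
            "non-standard residue codes %s mapped to gap", sorted(unknown_seen)
        )
    return "".join(out)


@dataclass(frozen=True)
class AlignedFamily:
    """One aligned protein family: equal-length gapped rows over 20 AA + gap."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentShapeError("an aligned family needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in count")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged alignment: row lengths {sorted(lengths)}")
        for r in self.rows:
            bad = set(r) - set(AMINO_ACIDS) - {GAP}
            if bad:
                raise ValueError(f"illegal symbols {sorted(bad)} in alignment row")

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], ids: Iterable[str] | None = None
    ) -> "AlignedFamily":
        rows = tuple(_canonicalize(s) for s in seqs)
        ids_t = tuple(ids) if ids is not None else tuple(f"seq{i+1}" for i in range(len(rows)))
        return cls(ids=ids_t, rows=rows)

    @property
    def length(self) -> int:
        """Number of alignment columns L."""
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_indices(self) -> np.ndarray:
        """Integer encoding, shape (n_sequences, L); residues 0..19, gap 20."""
        lut = np.full(128, 20, dtype=np.int8)
        for a, i in _AA_INDEX.items():
            lut[ord(a)] = i
        arr = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return lut[arr].reshape(self.n_sequences, self.length)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column residue frequencies plus the modal (consensus) sequence.

    ``frequencies[j]`` maps residue -> probability for column ``j``;
    columns that are entirely gaps under the ``exclude`` policy are listed
    in ``undefined_columns`` and carry the gap symbol in ``consensus``.
    """

    frequencies: tuple[dict[str, float], ...]
    consensus: str
    gap_policy: str
    undefined_columns: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for j, freqs in enumerate(self.frequencies):
            if j in self.undefined_columns:
                continue
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column {j} frequencies sum to {total}, not 1")
        if len(self.consensus) != len(self.frequencies):
            raise ValueError("consensus length != number of columns")


def read_alignment(
    path: str | Path, format: Literal["fasta", "stockholm"] = "fasta"
) -> AlignedFamily:
    """Read an aligned family from a FASTA or Stockholm file.

    Lower-case letters are upper-cased and both ``.`` and ``-`` become the
    canonical gap symbol, so Pfam-style full alignments parse directly.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:  # empty file, ragged rows, bad dialect
        raise AlignmentShapeError(f"cannot parse {path} as {format}: {exc}") from exc
    return AlignedFamily.from_sequences(
        (str(rec.seq) for rec in aln), ids=(rec.id for rec in aln)
    )


def build_consensus(
    fam: AlignedFamily, gap_policy: Literal["exclude", "count"] = "exclude"
) -> ConsensusProfile:
    """Column-wise residue frequencies and the modal consensus sequence.

    With ``gap_policy='exclude'`` (default) frequencies are taken over the
    non-gap characters of each column; ``'count'`` treats the gap as a 21st
    state.  Modal ties are broken by alphabetical residue order.  All-gap
    columns under ``exclude`` are flagged rather than fatal.
    """
    if gap_policy not in ("exclude", "count"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    freqs: list[dict[str, float]] = []
    consensus: list[str] = []
    undefined: list[int] = []
    for j in range(fam.length):
        col = fam.column(j)
        if gap_policy == "exclude":
            col = col.replace(GAP, "")
        if not col:
            undefined.append(j)
            freqs.append({})
            consensus.append(GAP)
            continue
        counts = Counter(col)
        n = len(col)
        table = {a: c / n for a, c in sorted(counts.items())}
        freqs.append(table)
        best = max(counts.items(), key=lambda kv: (kv[1], -_order(kv[0])))
        consensus.append(best[0])
    if undefined:
        logger.warning("all-gap columns under 'exclude' policy: %s", undefined)
    return ConsensusProfile(
        frequencies=tuple(freqs),
        consensus="".join(consensus),
        gap_policy=gap_policy,
        undefined_columns=tuple(undefined),
    )


def _order(symbol: str) -> int:
    # gap sorts after every residue so a residue always wins a tie with it
    return _AA_INDEX.get(symbol, len(AMINO_ACIDS))


def sequence_entropy(seq: str) -> float:
    """Compositional Shannon entropy of one sequence, in bits.

    Gaps are excluded from the composition; the sum runs over the residue
    types actually present, so the result is bounded by log2(20).
    """
    seq = _canonicalize(seq)
    residues = seq.replace(GAP, "")
    if not residues:
        raise ValueError("sequence contains no residues (all gaps)")
    counts = np.array(list(Counter(residues).values()), dtype=float)
    p = counts / counts.sum()
    return float(max(0.0, -(p * np.log2(p)).sum()))


def classify_order(
    entropy: float, threshold: float = DISORDER_THRESHOLD_BITS
) -> Literal["ordered", "disordered"]:
    """Order/disorder call: ordered iff entropy < threshold (strictly)."""
    if entropy < 0:
        raise ValueError(f"entropy must be non-negative, got {entropy}")
    return "ordered" if entropy < threshold else "disordered"


def entropy_report(
    fam: AlignedFamily,
    threshold: float = DISORDER_THRESHOLD_BITS,
    include_consensus: bool = True,
) -> pd.DataFrame:
    """Entropy and order/disorder class per family member (and consensus).

    Returns a DataFrame with columns ``id``, ``entropy_bits``, ``class``;
    the consensus row, when requested, is scored on the modal sequence of
    the gap-excluding consensus profile.
    """
    records = []
    for sid, row in zip(fam.ids, fam.rows):
        h = sequence_entropy(row)
        records.append({"id": sid, "entropy_bits": h, "class": classify_order(h, threshold)})
    if include_consensus:
        cons = build_consensus(fam).consensus
        h = sequence_entropy(cons)
        records.append(
            {"id": "__consensus__", "entropy_bits": h, "class": classify_order(h, threshold)}
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["threshold_bits"] = threshold
    return df
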