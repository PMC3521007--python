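"""Alignment containers, MOS ensemble scoring, and column-confidence filtering.

An ensemble here is a set of alternative multiple alignments of the *same*
sequences (as produced by running several aligners on one input). Quality
is judged by pair sharing: a residue pair aligned the same way by many
members of the ensemble is more likely correct. The multiple overlap score
(MOS) of one alignment is the mean, over its aligned residue pairs, of the
fraction of the other alignments asserting the same pair; the best
alignment is the MOS argmax.

The same pair-sharing evidence yields a per-column confidence score used
to drop unreliable columns before tree building (default threshold 0.93).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "GAP_CHARS",
    "read_alignment",
    "read_alignments",
    "write_alignment",
    "residue_pairs",
    "overlap_score",
    "mos_scores",
    "filter_columns",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class Alignment:
    """An ordered gapped sequence matrix; all rows equal length."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows (lengths {sorted(lengths)})")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, rows = zip(*pairs) if pairs else ((), ())
        return cls(tuple(ids), tuple(rows))

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return "".join(c for c in self.row(seq_id) if c not in GAP_CHARS)

    def ungapped_all(self) -> dict[str, str]:
        return {i: self.ungapped(i) for i in self.ids}

    def aligned_length(self, seq_id: str) -> int:
        """Number of residues (non-gap characters) in a row."""
        return len(self.ungapped(seq_id))

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        rows = tuple("".join(r[j] for j in indices) for r in self.rows)
        return Alignment(self.ids, rows)

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


# ---------------------------------------------------------------------------
# I/O (aligned FASTA and Stockholm via Biopython)


def _to_biopython(aln: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    )


def _from_biopython(msa: MultipleSeqAlignment) -> Alignment:
    return Alignment(
        tuple(rec.id for rec in msa), tuple(str(rec.seq) for rec in msa)
    )


def read_alignment(source: Union[str, TextIO], fmt: str = "fasta") -> Alignment:
    """Read one alignment (``fmt``: ``fasta`` or ``stockholm``)."""
    return _from_biopython(AlignIO.read(source, fmt))


def read_alignments(
    sources: Iterable[Union[str, TextIO]], fmt: str = "fasta"
) -> list[Alignment]:
    return [read_alignment(s, fmt) for s in sources]


def write_alignment(
    aln: Alignment, dest: Union[str, TextIO], fmt: str = "fasta"
) -> None:
    AlignIO.write(_to_biopython(aln), dest, fmt)


def alignment_to_string(aln: Alignment, fmt: str = "fasta") -> str:
    buf = io.StringIO()
    write_alignment(aln, buf, fmt)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Residue pairs and MOS

Pair = tuple[tuple[str, int], tuple[str, int]]


def _ungapped_positions(row: str) -> list[int]:
    """Per column: the 0-based ungapped position, or -1 for a gap."""
    out = []
    k = 0
    for c in row:
        if c in GAP_CHARS:
            out.append(-1)
        else:
            out.append(k)
            k += 1
    return out


def residue_pairs(aln: Alignment) -> set[Pair]:
    """The set of aligned residue pairs asserted by an alignment.

    Each pair is ``((idA, posA), (idB, posB))`` with ``idA < idB``
    lexicographically and positions 0-based in the ungapped sequences.
    ``|pairs| = Σ_columns k(k-1)/2`` with ``k`` the non-gap count.
    """
    cols = [_ungapped_positions(r) for r in aln.rows]
    order = sorted(range(aln.n_rows), key=lambda i: aln.ids[i])
    out: set[Pair] = set()
    for j in range(aln.n_cols):
        present = [(aln.ids[i], cols[i][j]) for i in order if cols[i][j] >= 0]
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                out.add((present[a], present[b]))
    return out


def _position_matrix(aln: Alignment, id_index: dict[str, int], stride: int):
    """Per-column sorted vectors of residue codes (rank·stride + position)."""
    n, L = aln.n_rows, aln.n_cols
    pos = np.full((n, L), -1, dtype=np.int64)
    order = sorted(range(n), key=lambda i: id_index[aln.ids[i]])
    for row_rank, i in enumerate(order):
        ungapped = _ungapped_positions(aln.rows[i])
        rank = id_index[aln.ids[i]]
        for j, p in enumerate(ungapped):
            if p >= 0:
                pos[row_rank, j] = rank * stride + p
    return pos


def _pair_codes(aln: Alignment, id_index: dict[str, int], stride: int):
    """Sorted integer-encoded residue pairs (fast path for MOS/filtering).

    Returns ``(codes, column_of)``: flat sorted-by-column pair codes and
    the originating column index of each pair. ``id_index`` maps id → rank
    in the shared lexicographic order; ``stride`` must exceed every
    ungapped sequence length.
    """
    pos = _position_matrix(aln, id_index, stride)
    width = len(id_index) * stride
    triu_cache: dict[int, tuple] = {}
    chunks = []
    col_chunks = []
    for j in range(aln.n_cols):
        col = pos[:, j]
        present = np.sort(col[col >= 0])
        k = len(present)
        if k < 2:
            continue
        if k not in triu_cache:
            triu_cache[k] = np.triu_indices(k, 1)
        iu, ju = triu_cache[k]
        codes = present[iu] * width + present[ju]
        chunks.append(codes)
        col_chunks.append(np.full(len(codes), j, dtype=np.int64))
    if not chunks:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    return np.concatenate(chunks), np.concatenate(col_chunks)


def _sorted_membership(sorted_ref, queries):
    """Boolean membership of ``queries`` in the sorted unique array."""
    if len(sorted_ref) == 0:
        return np.zeros(len(queries), dtype=bool)
    idx = np.searchsorted(sorted_ref, queries)
    idx = np.minimum(idx, len(sorted_ref) - 1)
    return sorted_ref[idx] == queries


def _ensemble_codes(ensemble: Sequence[Alignment]):
    base = ensemble[0]
    idset = set(base.ids)
    ungapped = base.ungapped_all()
    for aln in ensemble[1:]:
        if set(aln.ids) != idset:
            raise ValueError("ensemble alignments have mismatched sequence ids")
        if aln.ungapped_all() != ungapped:
            raise ValueError("ensemble alignments have mismatched sequences")
    id_index = {sid: k for k, sid in enumerate(sorted(idset))}
    stride = max((len(s) for s in ungapped.values()), default=1) + 1
    return [_pair_codes(a, id_index, stride) for a in ensemble]


def overlap_score(a: set, b: set) -> float:
    """Symmetric pairwise overlap: ``2|a∩b| / (|a|+|b|)``; 1 for two empty sets."""
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def mos_scores(ensemble: Sequence[Alignment]) -> tuple[list[float], int]:
    """Multiple overlap score of each ensemble member and the argmax index.

    ``MOS(A) = mean over p ∈ pairs(A) of (#other alignments containing p)/(N-1)``.
    Ties break toward the lowest index; an alignment with no residue pairs
    scores 0 (it asserts no evidence).
    """
    if len(ensemble) < 2:
        raise ValueError("MOS needs at least two alignments")
    codes = _ensemble_codes(ensemble)
    sorted_codes = [np.sort(c) for c, _cols in codes]
    n_other = len(ensemble) - 1
    scores: list[float] = []
    for i, (mine, _cols) in enumerate(codes):
        if len(mine) == 0:
            scores.append(0.0)
            continue
        hits = np.zeros(len(mine), dtype=np.int64)
        for j, other in enumerate(sorted_codes):
            if j != i:
                hits += _sorted_membership(other, mine)
        scores.append(float(hits.mean()) / n_other)
    best = max(range(len(scores)), key=lambda i: (scores[i], -i))
    return scores, best


def filter_columns(
    chosen: Alignment,
    ensemble: Sequence[Alignment],
    threshold: float = 0.93,
) -> tuple[Alignment, list[float]]:
    """Drop low-confidence columns of ``chosen`` by ensemble agreement.

    A column's score is the mean, over its residue pairs, of the fraction
    of the *other* ensemble members asserting the pair. Columns scoring
    below ``threshold`` — and columns with no evaluable pairs (fewer than
    two residues) — are removed. Returns the filtered alignment and the
    per-column scores of the original (``nan`` for pairless columns).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    members = [a for a in ensemble if a is not chosen]
    if not members:
        raise ValueError("ensemble must contain at least one other alignment")
    codes = _ensemble_codes([chosen] + members)
    mine, col_of = codes[0]
    other_sorted = [np.sort(c) for c, _cols in codes[1:]]
    n_other = len(other_sorted)

    scores = [float("nan")] * chosen.n_cols
    keep: list[int] = []
    if len(mine):
        hits = np.zeros(len(mine), dtype=np.int64)
        for other in other_sorted:
            hits += _sorted_membership(other, mine)
        per_col_hits = np.zeros(chosen.n_cols, dtype=np.int64)
        per_col_pairs = np.zeros(chosen.n_cols, dtype=np.int64)
        np.add.at(per_col_hits, col_of, hits)
        np.add.at(per_col_pairs, col_of, 1)
        for j in range(chosen.n_cols):
            if per_col_pairs[j] == 0:
                continue
            score = per_col_hits[j] / (per_col_pairs[j] * n_other)
            scores[j] = float(score)
            if score >= threshold:
                keep.append(j)
    return chosen.take_columns(keep), scores
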