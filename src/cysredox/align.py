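"""Global protein alignment and cross-species residue-position mapping.

Conserved-cysteine discovery needs a residue-level correspondence between a
mouse protein and its human ortholog.  For a *pair* of sequences the
principled tool is an optimal global alignment (Needleman–Wunsch with affine
gap penalties, Gotoh's algorithm); the residue map is then read off the
alignment columns where neither side is gapped.

The dynamic program is implemented here rather than delegated so that the
traceback tie-break is fixed (diagonal, then gap-in-b, then gap-in-a) and the
output fully deterministic; tests cross-check the score against both an
exhaustive enumeration oracle and Bio.Align.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# gap convention: a gap of length L costs gap_open + gap_extend*(L-1),
# i.e. gap_open is the full cost of the first gapped residue (Bio.Align style)
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its species tag."""

    id: str
    species: str  # "mouse" or "human"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")


@dataclass
class AlignmentResult:
    """A global alignment: gapped strings, score and per-column positions.

    ``column_map`` holds one ``(pos_a, pos_b)`` tuple per alignment column,
    1-based, with ``None`` on the gapped side.
    """

    aligned_a: str
    aligned_b: str
    score: float
    column_map: list[tuple[int | None, int | None]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


class ResidueMap:
    """Strictly increasing partial map from positions in a to positions in b.

    Both coordinates are 1-based.  Monotonicity is a structural guarantee of
    any alignment-derived map and is enforced on construction.
    """

    def __init__(self, pairs: list[tuple[int, int]]):
        for (a0, b0), (a1, b1) in zip(pairs, pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise ValueError(
                    f"residue map not strictly increasing: ({a0},{b0}) -> ({a1},{b1})"
                )
        self.pairs = list(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in set(map(tuple, self.pairs))

    def __eq__(self, other) -> bool:
        return isinstance(other, ResidueMap) and self.pairs == other.pairs

    def get(self, pos_a: int) -> int | None:
        """Return the b-position aligned to ``pos_a``, or None."""
        for a, b in self.pairs:
            if a == pos_a:
                return b
        return None

    def transpose(self) -> "ResidueMap":
        return ResidueMap([(b, a) for a, b in self.pairs])


def load_blosum62():
    return substitution_matrices.load("BLOSUM62")


def pair_by_identifier(
    records: list[SequenceRecord],
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Pair mouse and human records sharing a protein identifier.

    Ambiguous (many-to-many) pairings — more than one record per
    (identifier, species) — are rejected with an error rather than silently
    resolved; identifiers present in only one species are skipped with a
    warning.
    """
    import warnings

    by_key: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.id, rec.species), []).append(rec)
    dup = [k for k, v in by_key.items() if len(v) > 1]
    if dup:
        raise ValueError(f"ambiguous many-to-many pairing for {sorted(dup)}")
    pairs = []
    for pid in sorted({rec.id for rec in records}):
        mouse = by_key.get((pid, "mouse"))
        human = by_key.get((pid, "human"))
        if mouse and human:
            pairs.append((mouse[0], human[0]))
        else:
            warnings.warn(f"{pid}: present in only one species, skipped", stacklevel=2)
    return pairs


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    subst=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps (Gotoh).

    Parameters
    ----------
    subst : substitution matrix, optional
        Anything indexable as ``subst[res_a, res_b]``; defaults to BLOSUM62.
    gap_open, gap_extend : float
        Positive penalties.  A gap of length L costs
        ``gap_open + gap_extend * (L - 1)``.

    The traceback prefers, in order: residue–residue column, gap in b
    (consuming a), gap in a — making co-optimal alignments resolve
    deterministically.
    """
    if subst is None:
        subst = load_blosum62()
    sa, sb = a.sequence, b.sequence
    n, m = len(sa), len(sb)
    NEG = float("-inf")
    go, ge = float(gap_open), float(gap_extend)

    # substitution scores as plain floats, row per residue of a
    score_rows = []
    for si in sa:
        score_rows.append([float(subst[si, bj]) for bj in sb])

    # state matrices (lists of row lists): M residue-residue,
    # X gap in b (consumes a), Y gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -go - ge * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -go - ge * (j - 1)

    # pointer codes: which predecessor state fed each cell (0=M, 1=X, 2=Y);
    # ties resolve M > X > Y, giving the diagonal > gap-in-b > gap-in-a order
    ptr_m = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]

    for i in range(1, n + 1):
        srow = score_rows[i - 1]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Mc, Xc, Yc = M[i], X[i], Y[i]
        pm, px, py = ptr_m[i], ptr_x[i], ptr_y[i]
        for j in range(1, m + 1):
            jm1 = j - 1
            # M: diagonal from any state
            vm, vx, vy = Mp[jm1], Xp[jm1], Yp[jm1]
            if vm >= vx and vm >= vy:
                Mc[j] = vm + srow[jm1]
            elif vx >= vy:
                Mc[j] = vx + srow[jm1]
                pm[j] = 1
            else:
                Mc[j] = vy + srow[jm1]
                pm[j] = 2
            # X: gap in b (vertical)
            vm, vx, vy = Mp[j] - go, Xp[j] - ge, Yp[j] - go
            if vm >= vx and vm >= vy:
                Xc[j] = vm
            elif vx >= vy:
                Xc[j] = vx
                px[j] = 1
            else:
                Xc[j] = vy
                px[j] = 2
            # Y: gap in a (horizontal)
            vm, vx, vy = Mc[jm1] - go, Xc[jm1] - go, Yc[jm1] - ge
            if vm >= vx and vm >= vy:
                Yc[j] = vm
            elif vx >= vy:
                Yc[j] = vx
                py[j] = 1
            else:
                Yc[j] = vy
                py[j] = 2

    finals = (M[n][m], X[n][m], Y[n][m])
    state = 0 if finals[0] >= finals[1] and finals[0] >= finals[2] else (1 if finals[1] >= finals[2] else 2)
    score = float(finals[state])

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = ptr_m[i][j]
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            cols.append((i, j))
            i, j = i - 1, j - 1
        elif state == 1:
            prev = ptr_x[i][j] if j > 0 else 1
            out_a.append(sa[i - 1])
            out_b.append("-")
            cols.append((i, None))
            i -= 1
        else:
            prev = ptr_y[i][j] if i > 0 else 2
            out_a.append("-")
            out_b.append(sb[j - 1])
            cols.append((None, j))
            j -= 1
        state = prev
    out_a.reverse()
    out_b.reverse()
    cols.reverse()
    return AlignmentResult("".join(out_a), "".join(out_b), score, cols)


def map_positions(alignment: AlignmentResult) -> ResidueMap:
    """Residue map from alignment columns where neither side is gapped."""
    return ResidueMap(
        [(pa, pb) for pa, pb in alignment.column_map if pa is not None and pb is not None]
    )


def conserved_cysteines(
    a: SequenceRecord, b: SequenceRecord, rmap: ResidueMap
) -> list[tuple[int, int]]:
    """Aligned position pairs where both residues are cysteine.

    Returned ascending by the a-side (mouse) position.  A cysteine aligned to
    any other residue (e.g. a C→S substitution) is excluded: conservation
    requires C on both sides.
    """
    out = []
    for pa, pb in rmap:
        if pa < 1 or pa > len(a.sequence) or pb < 1 or pb > len(b.sequence):
            raise ValueError(f"map position ({pa},{pb}) out of sequence range")
        if a.sequence[pa - 1] == "C" and b.sequence[pb - 1] == "C":
            out.append((pa, pb))
    return out
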