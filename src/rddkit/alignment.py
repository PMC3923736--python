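"""Global pairwise alignment of clones against the spliced coding reference.

Clones are near-identical amplicons of one reference, so a pairwise global
alignment with affine gap costs (Gotoh's three-state dynamic programme)
replaces a multiple alignment: every clone is compared column-by-column to
the gDNA consensus.  Traceback ties are broken diagonal > deletion >
insertion and gap runs are then shifted to their leftmost equivalent
placement, so event positions are canonical and deterministic.

State conventions (ref = rows, query = columns):

* M  - ref base aligned to query base (diagonal)
* X  - ref base aligned to a gap in the query: a *deletion* from the clone
* Y  - query base aligned to a gap in the reference: an *insertion*

A gap of length L costs ``open + (L - 1) * extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seq_core import AlphabetError, _check_alphabet

logger = logging.getLogger("rddkit")

NEG = -1e12  # effectively -infinity; keeps arithmetic exact in float64


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring parameters (integers).

    Defaults discourage spurious indels in near-identical pairs.
    """

    match: int = 2
    mismatch: int = -2
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")


DEFAULT_PARAMS = AlignParams()


@dataclass
class AlignedPair:
    """One global alignment: equal-length rows over {A,C,G,T,-}."""

    ref_row: str
    query_row: str
    score: int

    def __post_init__(self):
        if len(self.ref_row) != len(self.query_row):
            raise ValueError("alignment rows differ in length")
        for r, q in zip(self.ref_row, self.query_row):
            if r == "-" and q == "-":
                raise ValueError("gap/gap column in alignment")

    @property
    def ref(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def query(self) -> str:
        return self.query_row.replace("-", "")


@dataclass
class ConsensusResult:
    """gDNA consensus over a reference plus positions of any disagreement."""

    consensus: str
    variable_positions: list


# ---------------------------------------------------------------------------
# Gotoh DP
# ---------------------------------------------------------------------------

def _fill_matrices(ref: str, query: str, p: AlignParams):
    n, m = len(ref), len(query)
    o, e = float(p.gap_open), float(p.gap_extend)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    qry_arr = np.frombuffer(query.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in query (deletion), moves i
    Y = np.full((n + 1, m + 1), NEG)  # gap in ref (insertion), moves j
    M[0, 0] = 0.0
    i_idx = np.arange(1, n + 1, dtype=float)
    j_idx = np.arange(1, m + 1, dtype=float)
    X[1:, 0] = o + (i_idx - 1) * e
    Y[0, 1:] = o + (j_idx - 1) * e

    je = np.arange(m + 1, dtype=float) * e
    for i in range(1, n + 1):
        sub = np.where(qry_arr == ref_arr[i - 1], float(p.match), float(p.mismatch))
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub + prev_best[:-1]
        X[i] = np.maximum(np.maximum(M[i - 1] + o, X[i - 1] + e), Y[i - 1] + o)
        X[i, 0] = o + (i - 1) * e
        # Y within the row is a running max: Y[j] = max(T[j], Y[j-1] + e)
        T = np.maximum(M[i, :-1], X[i, :-1]) + o
        V = np.empty(m + 1)
        V[0] = NEG
        V[1:] = T - je[1:]
        np.maximum.accumulate(V, out=V)
        Y[i, 1:] = V[1:] + je[1:]
        Y[i, 0] = NEG
        M[i, 0] = NEG
    return M, X, Y


def global_align(ref: str, query: str, params: AlignParams = DEFAULT_PARAMS) -> AlignedPair:
    """Optimal global alignment under affine-gap scoring.

    Deterministic traceback with tie-break diagonal > deletion > insertion,
    followed by left-normalisation of gap runs.
    """
    if not ref or not query:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(ref, "ref")
    _check_alphabet(query, "query")
    p = params
    M, X, Y = _fill_matrices(ref, query, p)
    n, m = len(ref), len(query)
    o, e = float(p.gap_open), float(p.gap_extend)

    i, j = n, m
    finals = [("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])]
    score = max(v for _, v in finals)
    state = next(s for s, v in finals if v == score)

    ref_cols, qry_cols = [], []
    while i > 0 or j > 0:
        if state == "M":
            ref_cols.append(ref[i - 1])
            qry_cols.append(query[j - 1])
            target = M[i, j] - (p.match if ref[i - 1] == query[j - 1] else p.mismatch)
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if v == target:
                    state = s
                    break
        elif state == "X":
            ref_cols.append(ref[i - 1])
            qry_cols.append("-")
            cur = X[i, j]
            i -= 1
            for s, v in (("M", M[i, j] + o), ("X", X[i, j] + e), ("Y", Y[i, j] + o)):
                if v == cur:
                    state = s
                    break
        else:  # Y
            ref_cols.append("-")
            qry_cols.append(query[j - 1])
            cur = Y[i, j]
            j -= 1
            for s, v in (("M", M[i, j] + o), ("X", X[i, j] + e), ("Y", Y[i, j] + o)):
                if v == cur:
                    state = s
                    break
    pair = AlignedPair("".join(reversed(ref_cols)), "".join(reversed(qry_cols)),
                       int(score))
    return left_normalize_gaps(pair)


def align_score(ref: str, query: str, params: AlignParams = DEFAULT_PARAMS) -> int:
    """Optimal score only (no traceback)."""
    M, X, Y = _fill_matrices(ref, query, params)
    return int(max(M[-1, -1], X[-1, -1], Y[-1, -1]))


# ---------------------------------------------------------------------------
# left-normalisation
# ---------------------------------------------------------------------------

def _shift_runs(gapped: str, other: str):
    """Shift every gap run in ``gapped`` leftward while the flanking base in
    ``other`` repeats (other[s-1] == other[e]); preserves score and the
    multiset of edit operations."""
    g = list(gapped)
    o = list(other)
    changed = False
    i = 0
    while i < len(g):
        if g[i] != "-":
            i += 1
            continue
        s = i
        while i < len(g) and g[i] == "-":
            i += 1
        e = i - 1
        while s > 0 and g[s - 1] != "-" and o[s - 1] != "-" and o[s - 1] == o[e]:
            # the aligned base just left of the run re-enters on the right
            g[s - 1], g[e] = g[e], g[s - 1]
            s -= 1
            e -= 1
            changed = True
        i = e + 1 if e + 1 > i else i
    return "".join(g), changed


def left_normalize_gaps(pair: AlignedPair) -> AlignedPair:
    """Shift every gap run to its leftmost equivalent placement."""
    ref_row, qry_row = pair.ref_row, pair.query_row
    while True:
        qry_row, ch1 = _shift_runs(qry_row, ref_row)   # deletions slide over ref
        ref_row, ch2 = _shift_runs(ref_row, qry_row)   # insertions slide over query
        if not (ch1 or ch2):
            break
    return AlignedPair(ref_row, qry_row, pair.score)


# ---------------------------------------------------------------------------
# gDNA consensus
# ---------------------------------------------------------------------------

def project_onto_ref(pair: AlignedPair) -> list:
    """Per reference position, the aligned clone symbol ('-' if deleted).

    Insertions (reference-gap columns) are not representable in reference
    coordinates and are ignored here.
    """
    out = []
    for r, q in zip(pair.ref_row, pair.query_row):
        if r != "-":
            out.append(q)
    return out


def build_gdna_consensus(ref: str, gdna_clones, params: AlignParams = DEFAULT_PARAMS) -> ConsensusResult:
    """Per-column majority base over aligned gDNA clones.

    Any disagreement among clones is recorded in ``variable_positions``
    (possible allelic variation) and those sites are later masked from RDD
    calling.  Majority ties are broken toward the reference base.
    """
    clones = list(gdna_clones)
    if not clones:
        raise ValueError("at least one gDNA clone required")
    columns = [project_onto_ref(global_align(ref, clone, params)) for clone in clones]
    consensus = []
    variable = []
    for pos0 in range(len(ref)):
        observed = [col[pos0] for col in columns]
        symbols = set(observed)
        if len(symbols) > 1:
            variable.append(pos0 + 1)
        counts = {}
        for b in observed:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == best)
        base = ref[pos0] if ref[pos0] in winners else winners[0]
        if base == "-":  # a majority deletion cannot enter a consensus string
            base = ref[pos0]
            if pos0 + 1 not in variable:
                variable.append(pos0 + 1)
        consensus.append(base)
    if variable:
        logger.info("gDNA consensus: %d variable position(s) flagged", len(variable))
    return ConsensusResult("".join(consensus), sorted(variable))
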