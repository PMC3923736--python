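"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

import rddkit as rk


@pytest.fixture
def rng():
    return np.random.default_rng(20140213)


@pytest.fixture
def small_config():
    return rk.SimConfig(seed=3, n_genes=2, clones_per_tissue=4, gdna_clones=4)


@pytest.fixture
def toy_ref(rng):
    return rk.make_coding_transcript(rng, 60, orf_offset=12, utr3_len=24,
                                     gene_id="toy")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_align_score(ref: str, query: str, p: rk.AlignParams) -> int:
    """Exhaustive optimum over all global alignments.

    Enumerates every monotone matching of ref/query positions; for each
    matching the unaligned characters between consecutive aligned columns
    must be gapped, and with gap_open <= gap_extend one contiguous run per
    sequence per segment is optimal, so its affine cost is closed-form.
    """
    n, m = len(ref), len(query)
    best = None
    for k in range(min(n, m) + 1):
        for ri in combinations(range(n), k):
            for qi in combinations(range(m), k):
                score = 0
                prev_r = prev_q = -1
                for a, b in list(zip(ri, qi)) + [(n, m)]:
                    gr, gq = a - prev_r - 1, b - prev_q - 1
                    if gr:
                        score += p.gap_open + (gr - 1) * p.gap_extend
                    if gq:
                        score += p.gap_open + (gq - 1) * p.gap_extend
                    if a < n:
                        score += p.match if ref[a] == query[b] else p.mismatch
                    prev_r, prev_q = a, b
                if best is None or score > best:
                    best = score
    return best


def brute_force_complete_linkage(X: np.ndarray, labels):
    """Naive agglomeration: repeatedly merge the pair of clusters with the
    smallest maximum pairwise Euclidean distance."""
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = max(D[i, j] for i in a for j in b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(labels[i] for i in a),
                       frozenset(labels[i] for i in b), d))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return merges


def oracle_effect_category(ref: rk.TranscriptRef, variant_cdna: str) -> str:
    """Independent effect classification via biopython translation."""
    from Bio.Seq import Seq

    def translate(seq, offset):
        trimmed = seq[offset:]
        trimmed = trimmed[:len(trimmed) - len(trimmed) % 3]
        aa = str(Seq(trimmed).translate())
        return aa.split("*")[0], "*" in aa

    native, _ = translate(ref.cdna, ref.orf_offset)
    variant, stop_found = translate(variant_cdna, ref.orf_offset)
    net = len(variant_cdna) - len(ref.cdna)
    if variant == native:
        return "silent"
    if net % 3 != 0:
        return "frameshift_early" if len(variant) < len(native) else "frameshift_late"
    if net < 0:
        return "motif_deletion"
    if net == 0 and len(variant) < len(native) and stop_found:
        return "stop_gain"
    return "missense"
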