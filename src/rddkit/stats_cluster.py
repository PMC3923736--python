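"""Tissue/gene tabulations, substitution spectrum, context bias, clustering.

The headline summaries of a clone-set RDD screen: a gene x tissue count
matrix with totals, the 12-class substitution spectrum, the proportion of
substitution sites with a 3'-adenosine neighbour (tested against the
reference's background A frequency with a two-sided binomial test),
synonymous/non-synonymous splits, per-clone and per-kb-per-clone RDD
rates, and a complete-linkage Euclidean dendrogram over tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import binomtest

from .seq_core import STANDARD_TABLE, TranscriptRef
from .synthetic_data import SUBSTITUTION_CLASSES

logger = logging.getLogger("rddkit")


# ---------------------------------------------------------------------------
# substitution spectrum
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionSpectrum:
    counts: dict                 # class -> count, all 12 classes present
    total: int

    @property
    def fraction_a_to_g(self) -> float:
        return self.counts["A>G"] / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": list(SUBSTITUTION_CLASSES),
                             "count": [self.counts[c] for c in SUBSTITUTION_CLASSES]})


def substitution_spectrum(events) -> SubstitutionSpectrum:
    """Counts of the 12 ordered substitution classes (indels ignored)."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for ev in events:
        if ev.kind == "substitution":
            counts[f"{ev.ref_allele}>{ev.alt_allele}"] += 1
    return SubstitutionSpectrum(counts=counts, total=sum(counts.values()))


# ---------------------------------------------------------------------------
# 3'-context bias
# ---------------------------------------------------------------------------

def three_prime_context_bias(events, ref: TranscriptRef):
    """Proportion of substitution sites whose 3' reference neighbour is A.

    Tested two-sided against the reference's own background A frequency at
    internal positions (a single planned test; no multiplicity correction).
    Returns ``(proportion, p_value, n_eligible)``.
    """
    cdna = ref.cdna
    eligible = [ev for ev in events
                if ev.kind == "substitution" and ev.pos < len(cdna)]
    if not eligible:
        raise ValueError("no substitution events away from the 3' terminus")
    hits = sum(1 for ev in eligible if cdna[ev.pos] == "A")
    background = cdna[1:].count("A") / (len(cdna) - 1)
    result = binomtest(hits, len(eligible), background, alternative="two-sided")
    return hits / len(eligible), result.pvalue, len(eligible)


# ---------------------------------------------------------------------------
# gene x tissue counts
# ---------------------------------------------------------------------------

@dataclass
class RDDMatrix:
    table: pd.DataFrame          # genes x tissues, integer counts, no margins

    @property
    def gene_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def tissue_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.table.values.sum())

    def with_totals(self) -> pd.DataFrame:
        out = self.table.copy()
        out["Total"] = self.gene_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


def gene_tissue_counts(events, genes=None, tissues=None) -> RDDMatrix:
    """Gene x tissue RDD count matrix (each event counts once)."""
    rows = [(ev.gene_id, ev.tissue) for ev in events]
    df = pd.DataFrame(rows, columns=["gene", "tissue"])
    table = (df.groupby(["gene", "tissue"]).size().unstack(fill_value=0)
             if len(df) else pd.DataFrame())
    if genes is not None:
        table = table.reindex(index=list(genes), fill_value=0)
    if tissues is not None:
        table = table.reindex(columns=list(tissues), fill_value=0)
    return RDDMatrix(table=table.fillna(0).astype(int))


# ---------------------------------------------------------------------------
# synonymous / non-synonymous split
# ---------------------------------------------------------------------------

def syn_nonsyn_counts(events, ref: TranscriptRef):
    """Partition ORF substitution events into synonymous / non-synonymous.

    Events outside the ORF (before the offset or past the stop codon) are
    counted in neither and logged.  A sense->stop change is non-synonymous.
    """
    syn = nonsyn = skipped = 0
    orf_start = ref.orf_offset + 1
    orf_end = ref.native_stop_base + 2           # include the stop codon
    for ev in events:
        if ev.kind != "substitution":
            continue
        if not orf_start <= ev.pos <= orf_end:
            skipped += 1
            continue
        idx0 = ev.pos - 1
        codon_start = ref.orf_offset + 3 * ((idx0 - ref.orf_offset) // 3)
        codon = ref.cdna[codon_start:codon_start + 3]
        offset_in_codon = idx0 - codon_start
        mutated = (codon[:offset_in_codon] + ev.alt_allele
                   + codon[offset_in_codon + 1:])
        if STANDARD_TABLE.aa(codon) == STANDARD_TABLE.aa(mutated):
            syn += 1
        else:
            nonsyn += 1
    if skipped:
        logger.info("syn/nonsyn: %d substitution(s) outside the ORF skipped", skipped)
    return syn, nonsyn


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def rdd_rate(events, n_clones: int, ref: TranscriptRef):
    """(events per clone, events per kb per clone)."""
    if n_clones < 1:
        raise ValueError("at least one clone required")
    n = sum(1 for _ in events)
    per_clone = n / n_clones
    per_kb_per_clone = per_clone / (len(ref.cdna) / 1000.0)
    return per_clone, per_kb_per_clone


# ---------------------------------------------------------------------------
# hierarchical clustering of tissues
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Complete-linkage agglomeration over tissues.

    ``merges`` holds (member_set_a, member_set_b, height) in merge order;
    heights are non-decreasing under complete linkage.
    """

    labels: list
    linkage: np.ndarray
    merges: list = field(default_factory=list)
    newick: str = ""

    @property
    def heights(self):
        return [h for _, _, h in self.merges]

    def outermost_leaf(self):
        """The label merged last as a singleton, if the final merge has one."""
        n = len(self.labels)
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        singles = [i for i in (a, b) if i < n]
        if len(singles) == 1:
            return self.labels[singles[0]]
        return None


def _merges_from_linkage(Z: np.ndarray, labels):
    n = len(labels)
    members = {i: frozenset([labels[i]]) for i in range(n)}
    merges = []
    for k, (a, b, h, _size) in enumerate(Z):
        left, right = members[int(a)], members[int(b)]
        merges.append((left, right, float(h)))
        members[n + k] = left | right
    return merges


def tissue_dendrogram(matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering of tissues on Euclidean distances.

    ``matrix`` is tissues x features (per-site event counts or the 12-class
    spectrum per tissue).  Returns merges with heights plus a Newick string
    (heights halved onto branches, midpoint convention).
    """
    if matrix.shape[0] < 2:
        raise ValueError("at least two tissues required for clustering")
    X = matrix.to_numpy(dtype=float)
    Z = sch.linkage(X, method="complete", metric="euclidean")
    labels = list(matrix.index)
    merges = _merges_from_linkage(Z, labels)
    from skbio.tree import TreeNode
    tree = TreeNode.from_linkage_matrix(Z, labels)
    newick = str(tree).strip()
    return Dendrogram(labels=labels, linkage=Z, merges=merges, newick=newick)


def spectrum_by_tissue(events) -> pd.DataFrame:
    """Tissues x 12-class substitution counts (alternative feature space)."""
    tissues = sorted({ev.tissue for ev in events})
    out = pd.DataFrame(0, index=tissues, columns=list(SUBSTITUTION_CLASSES))
    for ev in events:
        if ev.kind == "substitution":
            out.loc[ev.tissue, f"{ev.ref_allele}>{ev.alt_allele}"] += 1
    return out


def site_counts_by_tissue(events) -> pd.DataFrame:
    """Tissues x (gene, site) event counts — the default clustering features.

    Clones without any RDD contribute nothing, so they are implicitly
    excluded from the feature matrix.
    """
    tissues = sorted({ev.tissue for ev in events})
    sites = sorted({(ev.gene_id, ev.pos) for ev in events})
    out = pd.DataFrame(0, index=tissues,
                       columns=pd.MultiIndex.from_tuples(sites) if sites else [])
    for ev in events:
        out.loc[ev.tissue, (ev.gene_id, ev.pos)] += 1
    return out
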