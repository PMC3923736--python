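"""Call per-clone RNA-DNA differences and speak the RNA-level nomenclature.

Events are read off the aligned columns of one clone vs. the gDNA
consensus.  Positions are 1-based on the reference amplicon; a deletion is
anchored at its first deleted base and an insertion at the reference base
it follows.  Names follow the RNA-level dialect used for Sanger clone
variant tables:

* substitution        ``r.68c>a``
* single-base del     ``r.187a<``
* two-base del        ``r.115_116at<``
* longer del (range)  ``r.181-192ga<``  (first and last deleted base only)
* insertion           ``r.317a>``

The range form prints only the first and last deleted bases, so parsing it
recovers the full deleted allele only when the reference sequence is
supplied.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace

from .alignment import AlignedPair, ConsensusResult

logger = logging.getLogger("rddkit")


@dataclass
class RDDEvent:
    """One RNA-DNA difference observed in one clone."""

    clone_id: str
    gene_id: str
    tissue: str
    individual: str
    kind: str                    # substitution | insertion | deletion
    pos: int                     # 1-based on the reference amplicon
    ref_allele: str
    alt_allele: str
    rna_name: str = ""

    def __post_init__(self):
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1 \
                    or self.ref_allele == self.alt_allele:
                raise ValueError(f"bad substitution {self.ref_allele}>{self.alt_allele}")
        elif self.kind == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion needs ref allele and empty alt")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion needs alt allele and empty ref")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.pos < 1:
            raise ValueError("pos must be 1-based")
        if not self.rna_name:
            self.rna_name = rna_name(self)

    @property
    def end(self) -> int:
        """Last reference base touched (for deletions; pos otherwise)."""
        if self.kind == "deletion":
            return self.pos + len(self.ref_allele) - 1
        return self.pos

    def key(self):
        return (self.clone_id, self.kind, self.pos, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_events(consensus: ConsensusResult, pair: AlignedPair, clone_meta) -> list:
    """One event per differing alignment column (insertion runs collapsed).

    ``clone_meta`` supplies clone_id/gene_id/tissue/individual labels.
    Columns at consensus ``variable_positions`` (possible allelic variation)
    are skipped; deletions are emitted per column and merged afterwards by
    :func:`merge_deletion_runs`.
    """
    masked = set(consensus.variable_positions)
    events = []
    ref_pos = 0
    ins_run = []        # pending inserted bases
    ins_anchor = 0
    meta = dict(clone_id=clone_meta.clone_id, gene_id=clone_meta.gene_id,
                tissue=clone_meta.tissue, individual=clone_meta.individual)

    def flush_insertion():
        nonlocal ins_run
        if ins_run:
            if ins_anchor in masked:
                logger.debug("dropping insertion at masked position %d", ins_anchor)
            else:
                events.append(RDDEvent(kind="insertion", pos=max(ins_anchor, 1),
                                       ref_allele="", alt_allele="".join(ins_run),
                                       **meta))
            ins_run = []

    for r, q in zip(pair.ref_row, pair.query_row):
        if r == "-":
            if not ins_run:
                ins_anchor = ref_pos
            ins_run.append(q)
            continue
        flush_insertion()
        ref_pos += 1
        if q == r:
            continue
        if ref_pos in masked:
            logger.debug("dropping event at masked position %d", ref_pos)
            continue
        if q == "-":
            events.append(RDDEvent(kind="deletion", pos=ref_pos,
                                   ref_allele=r, alt_allele="", **meta))
        else:
            events.append(RDDEvent(kind="substitution", pos=ref_pos,
                                   ref_allele=r, alt_allele=q, **meta))
    flush_insertion()
    return events


def merge_deletion_runs(events) -> list:
    """Collapse maximal runs of adjacent single-base deletions in one clone.

    Input must be one clone's events sorted by position; substitutions and
    insertions pass through untouched.  The total deleted base count is
    conserved.
    """
    out = []
    run = None
    for ev in sorted(events, key=lambda e: (e.pos, e.kind)):
        if ev.kind != "deletion":
            out.append(ev)
            continue
        if run is not None and ev.pos == run.pos + len(run.ref_allele):
            run = replace(run, ref_allele=run.ref_allele + ev.ref_allele, rna_name="")
        else:
            if run is not None:
                out.append(run)
            run = ev
    if run is not None:
        out.append(run)
    return sorted(out, key=lambda e: e.pos)


def group_nearby_deletions(events, window: int = 3) -> list:
    """Report-level grouping of near-adjacent deletions (gap <= window).

    Returns lists of deletion events whose starts are within ``window`` of
    the previous deletion's end, reproducing display rows like a two-base
    deletion that skips an unchanged base.  Calling itself keeps the events
    separate; this only affects presentation.
    """
    dels = sorted((e for e in events if e.kind == "deletion"), key=lambda e: e.pos)
    groups = []
    for ev in dels:
        if groups and ev.pos - groups[-1][-1].end <= window:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    return groups


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

def rna_name(event) -> str:
    """RNA-level name for an event (see module docstring for the dialect)."""
    if event.kind == "substitution":
        return f"r.{event.pos}{event.ref_allele.lower()}>{event.alt_allele.lower()}"
    if event.kind == "insertion":
        return f"r.{event.pos}{event.alt_allele.lower()}>"
    ref = event.ref_allele.lower()
    if len(ref) == 1:
        return f"r.{event.pos}{ref}<"
    last = event.pos + len(ref) - 1
    if len(ref) == 2:
        return f"r.{event.pos}_{last}{ref}<"
    return f"r.{event.pos}-{last}{ref[0]}{ref[-1]}<"


_SUB_RE = re.compile(r"^r\.(\d+)([acgt])>([acgt])$")
_INS_RE = re.compile(r"^r\.(\d+)([acgt]+)>$")
_DEL1_RE = re.compile(r"^r\.(\d+)([acgt])<$")
_DEL2_RE = re.compile(r"^r\.(\d+)_(\d+)([acgt]{2})<$")
_DELR_RE = re.compile(r"^r\.(\d+)-(\d+)([acgt])([acgt])<$")


class NameParseError(ValueError):
    """A variant name does not match the RNA-level dialect."""


def parse_rna_name(name: str, ref_seq: str | None = None) -> dict:
    """Parse an RNA-level name back into event fields.

    Returns ``{"kind", "pos", "ref_allele", "alt_allele"}``.  For range
    deletions the interior bases are only printed as first/last; they are
    reconstructed from ``ref_seq`` when given, otherwise the interior is
    filled with ``"."`` placeholders.
    """
    m = _SUB_RE.match(name)
    if m:
        return {"kind": "substitution", "pos": int(m.group(1)),
                "ref_allele": m.group(2).upper(), "alt_allele": m.group(3).upper()}
    m = _DEL1_RE.match(name)
    if m:
        return {"kind": "deletion", "pos": int(m.group(1)),
                "ref_allele": m.group(2).upper(), "alt_allele": ""}
    m = _DEL2_RE.match(name)
    if m:
        p1, p2 = int(m.group(1)), int(m.group(2))
        if p2 != p1 + 1:
            raise NameParseError(f"{name}: two-base deletion must be adjacent")
        return {"kind": "deletion", "pos": p1,
                "ref_allele": m.group(3).upper(), "alt_allele": ""}
    m = _DELR_RE.match(name)
    if m:
        p1, p2 = int(m.group(1)), int(m.group(2))
        if p2 <= p1 + 1:
            raise NameParseError(f"{name}: range deletion must span >= 3 bases")
        first, last = m.group(3).upper(), m.group(4).upper()
        if ref_seq is not None:
            ref = ref_seq[p1 - 1:p2]
            if not (ref.startswith(first) and ref.endswith(last)):
                raise NameParseError(f"{name}: reference disagrees with printed bases")
        else:
            ref = first + "." * (p2 - p1 - 1) + last
        return {"kind": "deletion", "pos": p1, "ref_allele": ref, "alt_allele": ""}
    m = _INS_RE.match(name)
    if m:
        return {"kind": "insertion", "pos": int(m.group(1)),
                "ref_allele": "", "alt_allele": m.group(2).upper()}
    raise NameParseError(f"cannot parse RNA variant name {name!r}")


# ---------------------------------------------------------------------------
# site summaries
# ---------------------------------------------------------------------------

@dataclass
class SiteSummary:
    """Per-site recurrence of RDDs across tissues (one gene)."""

    pos: int
    substitutions: dict = field(default_factory=dict)  # tissue -> {alt: count}
    deletions: dict = field(default_factory=dict)      # tissue -> count
    insertions: dict = field(default_factory=dict)     # tissue -> count

    @property
    def tissues(self):
        keys = set(self.substitutions) | set(self.deletions) | set(self.insertions)
        return sorted(keys)


def summarize_sites(events, clones_per_tissue=None) -> list:
    """Per-site, per-tissue recurrence counts for one gene.

    Deletions count at every base they remove.  ``clones_per_tissue``
    (tissue -> clone count) is used only for a sanity check that no site
    recurs more often than it is covered.
    """
    genes = {e.gene_id for e in events}
    if len(genes) > 1:
        raise ValueError(f"events span several genes: {sorted(genes)}")
    sites = {}

    def site(pos):
        if pos not in sites:
            sites[pos] = SiteSummary(pos=pos)
        return sites[pos]

    for ev in events:
        if ev.kind == "substitution":
            per = site(ev.pos).substitutions.setdefault(ev.tissue, defaultdict(int))
            per[ev.alt_allele] += 1
        elif ev.kind == "deletion":
            for pos in range(ev.pos, ev.end + 1):
                s = site(pos)
                s.deletions[ev.tissue] = s.deletions.get(ev.tissue, 0) + 1
        else:
            s = site(ev.pos)
            s.insertions[ev.tissue] = s.insertions.get(ev.tissue, 0) + 1

    if clones_per_tissue:
        for s in sites.values():
            for tissue in s.tissues:
                total = sum(s.substitutions.get(tissue, {}).values()) \
                    + s.deletions.get(tissue, 0) + s.insertions.get(tissue, 0)
                if tissue in clones_per_tissue and total > clones_per_tissue[tissue]:
                    raise ValueError(
                        f"site {s.pos}: {total} events exceed "
                        f"{clones_per_tissue[tissue]} clones in {tissue}")
    return [sites[p] for p in sorted(sites)]


def site_tissue_sharing(summaries) -> dict:
    """How many sites are seen in exactly one tissue vs. two or more."""
    one = sum(1 for s in summaries if len(s.tissues) == 1)
    multi = sum(1 for s in summaries if len(s.tissues) >= 2)
    return {"one_tissue": one, "multi_tissue": multi}
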