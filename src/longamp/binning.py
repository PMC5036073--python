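"""Assignment of every classified read pair to a kept template cluster.

End+end pairs must resolve both of their tags to the same cluster; an
end+internal pair carries a single tag which is queried against the
consensus-tag index for its parsed end.  Matching is unique-best within a
small mismatch budget (default 1, mirroring the clustering radius): a tag
equally close to two clusters is left unassigned rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .demux import END_END, END_INTERNAL, ClassifiedPair
from .tag_cluster import TagCluster

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "__ambiguous__"

ROLE_END_END = "END_END"
ROLE_INTERNAL_F = "END_INTERNAL_F"
ROLE_INTERNAL_R = "END_INTERNAL_R"


def _variants(tag: str):
    for i, base in enumerate(tag):
        for b in "ACGT":
            if b != base:
                yield tag[:i] + b + tag[i + 1:]


class TagIndex:
    """Exact and distance-1 lookup of consensus tags, per end.

    Collisions (the same consensus tag on two kept clusters of one end —
    possible for equal-abundance survivors of the chimera filter) are
    recorded and answer every query as ambiguous.
    """

    def __init__(self, kept: Sequence[TagCluster], budget: int = 1):
        self.budget = budget
        self._exact: Dict[str, Dict[str, set]] = {"f": {}, "r": {}}
        self._near: Dict[str, Dict[str, set]] = {"f": {}, "r": {}}
        self.collisions: List[Tuple[str, str]] = []
        for c in kept:
            for end, tag in (("f", c.consensus_tag_f), ("r", c.consensus_tag_r)):
                self._exact[end].setdefault(tag, set()).add(c.cluster_id)
                if budget >= 1:
                    for v in _variants(tag):
                        self._near[end].setdefault(v, set()).add(c.cluster_id)
        for end in ("f", "r"):
            for tag, cids in self._exact[end].items():
                if len(cids) > 1:
                    self.collisions.append((end, tag))

    def lookup(self, tag: str, end: str) -> Optional[str]:
        """Unique best match for a tag: exact hits beat distance-1 hits;
        >= 2 equally good candidates or none within budget -> None."""
        exact = self._exact[end].get(tag)
        if exact:
            return next(iter(exact)) if len(exact) == 1 else None
        if self.budget >= 1:
            near = self._near[end].get(tag)
            if near and len(near) == 1:
                return next(iter(near))
        return None


def index_consensus_tags(kept: Sequence[TagCluster], budget: int = 1) -> TagIndex:
    return TagIndex(kept, budget=budget)


def assign_read_pair(cp: ClassifiedPair, index: TagIndex) -> str:
    """Cluster id for one END_END or END_INTERNAL pair, or UNASSIGNED."""
    if cp.fragment_class == END_END:
        cf = index.lookup(cp.forward_parse.tag, "f")
        cr = index.lookup(cp.reverse_parse.tag, "r")
        if cf is not None and cf == cr:
            return cf
        return UNASSIGNED
    if cp.fragment_class == END_INTERNAL:
        if cp.forward_parse is not None:
            cid = index.lookup(cp.forward_parse.tag, "f")
        else:
            cid = index.lookup(cp.reverse_parse.tag, "r")
        return cid if cid is not None else UNASSIGNED
    return UNASSIGNED


@dataclass
class TemplateBin:
    """All reads attributed to one progenitor template molecule."""

    cluster_id: str
    sample: str
    members: list = field(default_factory=list)  # (ClassifiedPair, role)

    @property
    def end_end_count(self) -> int:
        return sum(1 for _, role in self.members if role == ROLE_END_END)

    @property
    def internal_count(self) -> int:
        return sum(1 for _, role in self.members if role != ROLE_END_END)


def bin_reads(classified: Iterable[ClassifiedPair], kept: Sequence[TagCluster],
              budget: int = 1) -> Dict[str, TemplateBin]:
    """Partition classified pairs over kept clusters (each pair lands in at
    most one bin; reads matching only discarded clusters are dropped)."""
    index = TagIndex(kept, budget=budget)
    bins = {c.cluster_id: TemplateBin(c.cluster_id, c.sample) for c in kept}
    for cp in classified:
        if cp.fragment_class not in (END_END, END_INTERNAL):
            continue
        cid = assign_read_pair(cp, index)
        if cid == UNASSIGNED:
            continue
        if cp.fragment_class == END_END:
            role = ROLE_END_END
        elif cp.forward_parse is not None:
            role = ROLE_INTERNAL_F
        else:
            role = ROLE_INTERNAL_R
        bins[cid].members.append((cp, role))
    return bins
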