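"""Classification of NUMTs into insertion / duplicate types and complex
clusters.

A *duplicate-type* NUMT arose from another NUMT by nuclear duplication: in
that case homology between the two NUMTs extends into the nuclear DNA that
flanks them, and the flank similarity matches the NUMT similarity.  A
*complex NUMT* is a chain of nearby fragments on one scaffold that are
co-oriented and syntenic with one mitochondrial region and are inferred to
descend from a single insertion event subsequently fragmented (typically by
TE insertion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from ._align import encode, revcomp, sw_local
from .homology_search import AlignmentHit

__all__ = [
    "NumtRecord",
    "ComplexCluster",
    "DuplicateFamily",
    "ClassifyParams",
    "records_from_hits",
    "cluster_complex",
    "detect_duplicates",
    "label_types",
    "with_cluster_ids",
    "write_numt_tsv",
]


@dataclass(frozen=True)
class NumtRecord:
    """One detected NUMT with its (eventual) classification."""

    numt_id: str
    scaffold: str
    nuc_interval: tuple[int, int]
    strand: str
    mito_interval: tuple[int, int]
    identity: float
    evalue: float
    type_label: str = "unassigned"  # insertion | duplicate | unassigned
    cluster_id: str | None = None
    family_id: str | None = None

    @property
    def length(self) -> int:
        return self.nuc_interval[1] - self.nuc_interval[0]


@dataclass(frozen=True)
class ComplexCluster:
    """An ordered chain of NUMT fragments from one inferred insertion event."""

    cluster_id: str
    scaffold: str
    member_ids: tuple[str, ...]
    strand: str
    mito_span: tuple[int, int]
    gaps: tuple[int, ...]


@dataclass(frozen=True)
class PairEvidence:
    pair: tuple[str, str]
    numt_similarity: float
    left_flank_similarity: float | None
    right_flank_similarity: float | None
    flank_homology_len: int


@dataclass(frozen=True)
class DuplicateFamily:
    """NUMTs related by post-insertion nuclear duplication."""

    family_id: str
    member_ids: tuple[str, ...]
    evidence: tuple[PairEvidence, ...]


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds for duplicate detection and complex-cluster chaining.

    ``max_gap`` is the maximum run of non-mitochondrial DNA between members
    of one cluster (default 10 kb).  The flank thresholds govern duplicate
    detection: flanks of ``flank_len`` bp are compared, a duplication link
    requires a homologous flank segment of at least ``min_flank_homology``
    bp contiguous with the NUMT boundary (within ``boundary_slop`` bp), and
    the flank similarity must match the NUMT similarity within
    ``similarity_tolerance``.
    """

    max_gap: int = 10_000
    flank_len: int = 1_000
    min_flank_homology: int = 100
    similarity_tolerance: float = 0.05
    dup_min_numt_similarity: float = 0.80
    boundary_slop: int = 20
    synteny_slop: int = 20

    def __post_init__(self) -> None:
        if min(self.max_gap, self.flank_len, self.min_flank_homology) <= 0:
            raise ValueError("lengths must be positive")
        if not (0 < self.similarity_tolerance < 1):
            raise ValueError("similarity_tolerance must be in (0, 1)")
        if not (0 < self.dup_min_numt_similarity <= 1):
            raise ValueError("dup_min_numt_similarity must be in (0, 1]")


def records_from_hits(hits: Sequence[AlignmentHit]) -> list[NumtRecord]:
    """Number filtered hits into NumtRecords, ordered by (scaffold, start)."""
    ordered = sorted(hits, key=lambda h: (h.scaffold, h.nuc_interval))
    return [
        NumtRecord(
            numt_id=f"NUMT_{i:05d}",
            scaffold=h.scaffold,
            nuc_interval=h.nuc_interval,
            strand=h.strand,
            mito_interval=h.mito_interval,
            identity=h.identity,
            evalue=h.evalue,
        )
        for i, h in enumerate(ordered, 1)
    ]


# ---------------------------------------------------------------------------
# complex clusters


def cluster_complex(numts: Sequence[NumtRecord], params: ClassifyParams | None = None) -> list[ComplexCluster]:
    """Chain fragments of single insertion events into complex clusters.

    Greedy left-to-right chaining per scaffold.  The next NUMT extends the
    current chain iff (1) it starts less than ``max_gap`` bp after the
    previous member ends, (2) it lies on the same strand, and (3) synteny
    holds: mitochondrial coordinates advance with the scaffold (strictly
    increasing, non-overlapping mito intervals for '+' chains; decreasing
    for '-').  Because local alignments can over-extend a base or two into
    the inserted DNA at a fragment boundary, mito intervals may overlap by
    up to ``synteny_slop`` bp (default 20); substantially overlapping
    (re-duplicated) fragments still break the chain.  Chains of two or more
    members become clusters.
    """
    params = params or ClassifyParams()
    by_scaf: dict[str, list[NumtRecord]] = {}
    for n in numts:
        lst = by_scaf.setdefault(n.scaffold, [])
        if lst and n.nuc_interval[0] < lst[-1].nuc_interval[0]:
            raise ValueError(f"NUMTs on {n.scaffold} are not sorted by start")
        lst.append(n)

    clusters: list[ComplexCluster] = []

    def _emit(chain: list[NumtRecord]) -> None:
        if len(chain) < 2:
            return
        cid = f"CC_{len(clusters) + 1:04d}"
        clusters.append(
            ComplexCluster(
                cluster_id=cid,
                scaffold=chain[0].scaffold,
                member_ids=tuple(m.numt_id for m in chain),
                strand=chain[0].strand,
                mito_span=(
                    min(m.mito_interval[0] for m in chain),
                    max(m.mito_interval[1] for m in chain),
                ),
                gaps=tuple(
                    b.nuc_interval[0] - a.nuc_interval[1] for a, b in zip(chain, chain[1:])
                ),
            )
        )

    for scaf in sorted(by_scaf):
        chain: list[NumtRecord] = []
        for n in by_scaf[scaf]:
            if chain:
                prev = chain[-1]
                gap = n.nuc_interval[0] - prev.nuc_interval[1]
                slop = params.synteny_slop
                if n.strand == "+":
                    syntenic = (
                        n.mito_interval[0] > prev.mito_interval[0]
                        and n.mito_interval[1] > prev.mito_interval[1]
                        and n.mito_interval[0] >= prev.mito_interval[1] - slop
                    )
                else:
                    syntenic = (
                        n.mito_interval[1] < prev.mito_interval[1]
                        and n.mito_interval[0] < prev.mito_interval[0]
                        and n.mito_interval[1] <= prev.mito_interval[0] + slop
                    )
                if 0 <= gap < params.max_gap and n.strand == prev.strand and syntenic:
                    chain.append(n)
                    continue
                _emit(chain)
            chain = [n]
        _emit(chain)
    return clusters


def with_cluster_ids(numts: Sequence[NumtRecord], clusters: Sequence[ComplexCluster]) -> list[NumtRecord]:
    """Return copies of the records carrying their cluster_id (if any)."""
    cid = {}
    for c in clusters:
        for m in c.member_ids:
            cid[m] = c.cluster_id
    return [replace(n, cluster_id=cid.get(n.numt_id)) for n in numts]


# ---------------------------------------------------------------------------
# duplicate families


def _local_stats(a: str, b: str):
    """Best local alignment of a vs b under the scan scoring scheme
    (+1/-2, gap 5+2L): (identity, columns, a_range, b_range), or None."""
    if not a or not b:
        return None
    score, mat, mis, gaps, a0, a1, b0, b1 = sw_local(encode(a), encode(b), 1, -2, 5, 2)
    cols = mat + mis + gaps
    if score <= 0 or cols == 0:
        return None
    return mat / cols, cols, (int(a0), int(a1)), (int(b0), int(b1))


def _oriented_parts(n: NumtRecord, genome: Mapping[str, str], flank_len: int) -> tuple[str, str, str]:
    """NUMT sequence and flanks in mitochondrial orientation.

    Returns (left_flank, numt, right_flank) where 'left' precedes the NUMT
    when reading in the orientation that matches the mitochondrial forward
    strand.  Flanks are truncated at scaffold ends.
    """
    seq = genome[n.scaffold]
    s, e = n.nuc_interval
    body = seq[s:e]
    up = seq[max(0, s - flank_len) : s]
    down = seq[e : e + flank_len]
    if n.strand == "+":
        return up, body, down
    return revcomp(down), revcomp(body), revcomp(up)


def _mito_overlap_frac(a: NumtRecord, b: NumtRecord) -> float:
    lo = max(a.mito_interval[0], b.mito_interval[0])
    hi = min(a.mito_interval[1], b.mito_interval[1])
    if hi <= lo:
        return 0.0
    shorter = min(a.mito_interval[1] - a.mito_interval[0], b.mito_interval[1] - b.mito_interval[0])
    return (hi - lo) / shorter


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_duplicates(
    numts: Sequence[NumtRecord],
    genome: Mapping[str, str],
    params: ClassifyParams | None = None,
) -> list[DuplicateFamily]:
    """Find duplication-linked NUMT pairs and group them into families.

    Two NUMTs are duplication-linked when (1) their local alignment identity
    is at least ``dup_min_numt_similarity`` over at least half of the shorter
    NUMT, and (2) at least one pair of corresponding flanks (strand-aware)
    shows a homologous segment of >= ``min_flank_homology`` bp contiguous
    with the NUMT boundary whose identity matches the NUMT identity within
    ``similarity_tolerance``.  Families are the connected components of the
    link graph.
    """
    params = params or ClassifyParams()
    ids = [n.numt_id for n in numts]
    if len(set(ids)) != len(ids):
        raise ValueError("NUMT ids are not unique")

    parts = {n.numt_id: _oriented_parts(n, genome, params.flank_len) for n in numts}
    uf = _UnionFind(ids)
    links: list[PairEvidence] = []

    ordered = sorted(numts, key=lambda n: (n.scaffold, n.nuc_interval))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            # duplicates descend from the same mitochondrial segment
            if _mito_overlap_frac(a, b) < 0.5:
                continue
            la, na, ra = parts[a.numt_id]
            lb, nb, rb = parts[b.numt_id]
            st = _local_stats(na, nb)
            if st is None:
                continue
            numt_sim, cols, _, _ = st
            if numt_sim < params.dup_min_numt_similarity or cols < 0.5 * min(len(na), len(nb)):
                continue

            def _flank_ok(fa: str, fb: str, side: str):
                st = _local_stats(fa, fb)
                if st is None:
                    return None, False
                sim, fcols, ra_, rb_ = st
                if side == "left":  # boundary at the end of the flank string
                    contiguous = (len(fa) - ra_[1] <= params.boundary_slop
                                  and len(fb) - rb_[1] <= params.boundary_slop)
                else:  # boundary at the start
                    contiguous = ra_[0] <= params.boundary_slop and rb_[0] <= params.boundary_slop
                ok = (
                    fcols >= params.min_flank_homology
                    and contiguous
                    and abs(sim - numt_sim) <= params.similarity_tolerance
                )
                return (sim, fcols), ok

            left_ev, left_ok = _flank_ok(la, lb, "left")
            right_ev, right_ok = _flank_ok(ra, rb, "right")
            if left_ok or right_ok:
                uf.union(a.numt_id, b.numt_id)
                fl = max(
                    left_ev[1] if left_ok else 0,
                    right_ev[1] if right_ok else 0,
                )
                links.append(
                    PairEvidence(
                        pair=(a.numt_id, b.numt_id),
                        numt_similarity=numt_sim,
                        left_flank_similarity=left_ev[0] if left_ev else None,
                        right_flank_similarity=right_ev[0] if right_ev else None,
                        flank_homology_len=fl,
                    )
                )

    groups: dict[str, list[str]] = {}
    for nid in ids:
        groups.setdefault(uf.find(nid), []).append(nid)
    families: list[DuplicateFamily] = []
    for root in sorted(groups):
        members = sorted(groups[root])
        if len(members) < 2:
            continue
        fid = f"FAM_{len(families) + 1:04d}"
        ev = tuple(e for e in links if e.pair[0] in members and e.pair[1] in members)
        families.append(DuplicateFamily(family_id=fid, member_ids=tuple(members), evidence=ev))
    return families


def label_types(
    numts: Sequence[NumtRecord],
    families: Sequence[DuplicateFamily],
    originals_as_insertion: bool = True,
) -> list[NumtRecord]:
    """Assign every NUMT its insertion/duplicate type label.

    Within each duplicate family the member most similar to the
    mitochondrial genome (ties: lower E-value, then smaller coordinate) is
    taken as the putative original and labelled ``insertion``; the rest are
    ``duplicate``.  With ``originals_as_insertion=False`` whole families are
    labelled duplicate.  NUMTs outside any family are insertion type, so
    insertion + duplicate = total always holds.
    """
    by_id = {n.numt_id: n for n in numts}
    fam_of: dict[str, str] = {}
    dup_ids: set[str] = set()
    for fam in families:
        members = [by_id[m] for m in fam.member_ids]
        for m in members:
            fam_of[m.numt_id] = fam.family_id
        if originals_as_insertion:
            original = min(
                members, key=lambda m: (-m.identity, m.evalue, m.scaffold, m.nuc_interval)
            )
            dup_ids.update(m.numt_id for m in members if m.numt_id != original.numt_id)
        else:
            dup_ids.update(m.numt_id for m in members)
    return [
        replace(
            n,
            type_label="duplicate" if n.numt_id in dup_ids else "insertion",
            family_id=fam_of.get(n.numt_id),
        )
        for n in numts
    ]


def write_numt_tsv(path, numts: Sequence[NumtRecord]) -> None:
    """Classified NUMT table; coordinates 1-based inclusive on output."""
    with open(path, "w") as fh:
        fh.write(
            "numt_id\tscaffold\tstart\tend\tstrand\tmito_start\tmito_end\t"
            "identity\tevalue\ttype\tfamily_id\tcluster_id\n"
        )
        for n in numts:
            fh.write(
                f"{n.numt_id}\t{n.scaffold}\t{n.nuc_interval[0] + 1}\t{n.nuc_interval[1]}\t"
                f"{n.strand}\t{n.mito_interval[0] + 1}\t{n.mito_interval[1]}\t"
                f"{n.identity:.4f}\t{n.evalue:.3g}\t{n.type_label}\t"
                f"{n.family_id or '.'}\t{n.cluster_id or '.'}\n"
            )
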