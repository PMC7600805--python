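"""Genomic context of NUMTs: flank AT profiles, gene-relative position,
NUMT/TE density tracks and TE content of NUMT neighbourhoods.

Consumes gene annotation (GFF3) and repeat annotation (RepeatMasker ``.out``)
and works on the same 0-based half-open coordinates as the rest of the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._align import encode

__all__ = [
    "TEAnnotation",
    "GeneModel",
    "ATProfile",
    "DensityWindow",
    "PositionSummary",
    "TEVicinity",
    "at_profile",
    "flank_at_test",
    "classify_position",
    "density_tracks",
    "te_vicinity",
    "read_repeatmasker_out",
    "read_gff",
    "write_density_bed",
]


@dataclass(frozen=True)
class TEAnnotation:
    """One repeat interval from a RepeatMasker-style annotation."""

    scaffold: str
    interval: tuple[int, int]
    te_name: str
    superfamily: str
    divergence: float | None = None


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon and CDS intervals (all 0-based half-open)."""

    gene_id: str
    scaffold: str
    gene_interval: tuple[int, int]
    strand: str
    exon_intervals: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return self.gene_interval[1] - self.gene_interval[0]


@dataclass
class ATProfile:
    """Mean AT content in sliding windows around NUMT boundaries.

    ``positions`` are window-start offsets: relative to the NUMT start for the
    ``start`` segment (negative = upstream flank, non-negative = first bases
    of the NUMT) and relative to the NUMT end for the ``end`` segment
    (negative = last bases of the NUMT, non-negative = downstream flank).
    """

    positions: np.ndarray
    segments: np.ndarray
    mean_at: np.ndarray
    n_numts: int
    window: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment": self.segments, "offset": self.positions, "mean_at": self.mean_at}
        )


@dataclass(frozen=True)
class DensityWindow:
    scaffold: str
    window_interval: tuple[int, int]
    numt_coverage: float
    te_coverage: float


@dataclass(frozen=True)
class PositionSummary:
    """Counts of NUMTs by genomic compartment (Table-1 shape)."""

    n_intergenic: int
    prop_intergenic: float
    n_intronic: int
    prop_intronic: float
    n_genes_hit: int
    n_cds: int

    @property
    def total(self) -> int:
        return self.n_intergenic + self.n_intronic + self.n_cds


@dataclass
class TEVicinity:
    """Per-unit TE neighbourhood calls plus the derived proportions."""

    table: pd.DataFrame
    prop_with_te: float
    superfamily_props: dict[str, float]
    n_units: int


# ---------------------------------------------------------------------------
# sequence helpers


def _at_cumsum(seq: str) -> np.ndarray:
    codes = encode(seq)
    at = ((codes == 0) | (codes == 3)).astype(np.int64)
    cs = np.zeros(len(at) + 1, dtype=np.int64)
    np.cumsum(at, out=cs[1:])
    return cs


def _window_at(cs: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    return (cs[starts + window] - cs[starts]) / window


def _unit_coords(n) -> tuple[str, int, int]:
    return n.scaffold, n.nuc_interval[0], n.nuc_interval[1]


# ---------------------------------------------------------------------------
# AT profiles and the flank AT test


def at_profile(numts: Sequence, genome: Mapping[str, str], flank: int = 250, end: int = 50, window: int = 5) -> ATProfile:
    """Mean AT content in sliding ``window``-bp windows (step 1) across the
    ``flank`` bp outside and the first/last ``end`` bp inside each NUMT.

    Windows are taken on the genome itself, so they slide across the NUMT
    boundary; flanks truncated by a scaffold edge contribute only their
    defined windows.  NUMTs shorter than ``2*end`` contribute a truncated
    interior.
    """
    if not numts:
        raise ValueError("at_profile requires at least one NUMT")
    cs_cache = {name: _at_cumsum(seq) for name, seq in genome.items() if any(
        _unit_coords(n)[0] == name for n in numts)}

    start_off = np.arange(-flank, end - window + 1)
    end_off = np.arange(-end, flank - window + 1)
    sums_s = np.zeros(len(start_off))
    cnts_s = np.zeros(len(start_off))
    sums_e = np.zeros(len(end_off))
    cnts_e = np.zeros(len(end_off))

    for n in numts:
        scaf, s, e = _unit_coords(n)
        cs = cs_cache[scaf]
        L = len(cs) - 1
        nlen = e - s
        interior = min(end, nlen)
        # start segment: window starts in [s - flank, s + interior - window]
        off = start_off[start_off <= interior - window]
        pos = s + off
        ok = (pos >= 0) & (pos + window <= L)
        if ok.any():
            vals = _window_at(cs, pos[ok], window)
            idx = np.nonzero(start_off <= interior - window)[0][ok]
            sums_s[idx] += vals
            cnts_s[idx] += 1
        # end segment: window starts in [e - interior, e + flank - window]
        off = end_off[end_off >= -interior]
        pos = e + off
        ok = (pos >= 0) & (pos + window <= L)
        if ok.any():
            vals = _window_at(cs, pos[ok], window)
            idx = np.nonzero(end_off >= -interior)[0][ok]
            sums_e[idx] += vals
            cnts_e[idx] += 1

    with np.errstate(invalid="ignore"):
        mean_s = np.where(cnts_s > 0, sums_s / np.maximum(cnts_s, 1), np.nan)
        mean_e = np.where(cnts_e > 0, sums_e / np.maximum(cnts_e, 1), np.nan)
    return ATProfile(
        positions=np.concatenate([start_off, end_off]),
        segments=np.array(["start"] * len(start_off) + ["end"] * len(end_off)),
        mean_at=np.concatenate([mean_s, mean_e]),
        n_numts=len(numts),
        window=window,
    )


def flank_at_test(
    numts: Sequence,
    genome: Mapping[str, str],
    flank: int = 10,
    reference: str = "control",
    seed: int = 0,
):
    """Paired one-sided Wilcoxon signed-rank test of flank AT enrichment.

    For each NUMT the mean AT of its two ``flank``-bp flanks (pooled,
    truncated at scaffold edges) is compared against the host scaffold's
    average AT; the alternative is that flanks are AT-richer.

    With ``reference="control"`` (default) each NUMT is paired with one
    random control window of the same total width from the same scaffold.
    Under random placement the paired difference is sign-symmetric by
    construction, so the signed-rank null is exact.  Comparing each flank
    against the scaffold-wide mean instead (``reference="scaffold_mean"``)
    is the naive reading of the contrast, but it is not calibrated: flank
    AT lies on a lattice (k / 2*flank), and the large tied group at the
    lattice point nearest the mean flips sign with the mean-estimation
    error as a block, overdispersing the statistic.  Control positions are
    drawn deterministically from ``seed``.

    Exact null for n <= 25 without ties, normal approximation with
    continuity correction otherwise.  If every difference is zero the test
    is degenerate and p = 1 is reported with the ``degenerate`` flag set.
    """
    from fractions import Fraction

    from .comparative_stats import _signed_rank

    if len(numts) < 6:
        raise ValueError("flank_at_test requires at least 6 NUMTs")
    if reference not in ("control", "scaffold_mean"):
        raise ValueError("reference must be 'control' or 'scaffold_mean'")
    rng = np.random.default_rng(seed)
    scafs = {_unit_coords(n)[0] for n in numts}
    cs_cache = {name: _at_cumsum(genome[name]) for name in scafs}
    scaf_mean = {name: Fraction(int(cs[-1]), len(cs) - 1) for name, cs in cs_cache.items()}

    # exact rational arithmetic: float rounding of lattice AT values breaks
    # mirror ties |x - ref| == |ref - y| in a systematically signed way
    diffs: list[Fraction] = []
    for n in numts:
        scaf, s, e = _unit_coords(n)
        cs = cs_cache[scaf]
        L = len(cs) - 1
        lo = max(0, s - flank)
        hi = min(L, e + flank)
        at = int((cs[s] - cs[lo]) + (cs[hi] - cs[e]))
        nb = (s - lo) + (hi - e)
        if nb == 0:
            continue
        if reference == "control":
            cpos = int(rng.integers(0, L - nb + 1))
            ref = Fraction(int(cs[cpos + nb] - cs[cpos]), nb)
        else:
            ref = scaf_mean[scaf]
        diffs.append(Fraction(at, nb) - ref)
    # sign-preserving dense ranks of |diff|: identical Wilcoxon statistic,
    # exact ties preserved
    mags = sorted({abs(d) for d in diffs})
    rank_of = {v: float(i + 1) for i, v in enumerate(mags)}
    arr = np.array([(d > 0) * rank_of[abs(d)] - (d < 0) * rank_of[abs(d)] for d in diffs])
    return _signed_rank(arr, "greater")


# ---------------------------------------------------------------------------
# gene-relative position


def classify_position(numts: Sequence, genes: Sequence[GeneModel]):
    """Assign each NUMT to coding / intronic / intergenic space.

    A NUMT is ``coding`` if it overlaps any CDS interval by >= 1 bp, else
    ``intronic`` if it overlaps any gene interval, else ``intergenic``
    (precedence CDS > intron > intergenic).  Overlapping gene models are
    resolved by longest-gene precedence.  Returns ``(PositionSummary,
    labels)`` where labels is a list aligned with ``numts``.
    """
    numts = list(numts)
    if genes and numts:
        if not ({g.scaffold for g in genes} & {_unit_coords(n)[0] for n in numts}):
            raise ValueError("NUMT and gene annotations share no scaffold; wrong GFF?")
    gene_trees: dict[str, IntervalTree] = {}
    cds_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gs, ge = g.gene_interval
        gene_trees.setdefault(g.scaffold, IntervalTree()).addi(gs, ge, g)
        for cs_, ce in g.cds_intervals:
            cds_trees.setdefault(g.scaffold, IntervalTree()).addi(cs_, ce, g)

    labels: list[str] = []
    genes_hit: set[str] = set()
    n_cds = n_intron = n_inter = 0
    for n in numts:
        scaf, s, e = _unit_coords(n)
        if scaf in cds_trees and cds_trees[scaf].overlap(s, e):
            labels.append("coding")
            n_cds += 1
            continue
        ovl = gene_trees[scaf].overlap(s, e) if scaf in gene_trees else set()
        if ovl:
            labels.append("intronic")
            n_intron += 1
            host = max(ovl, key=lambda iv: (iv.data.length, iv.data.gene_id))
            genes_hit.add(host.data.gene_id)
        else:
            labels.append("intergenic")
            n_inter += 1
    total = max(len(numts), 1)
    summary = PositionSummary(
        n_intergenic=n_inter,
        prop_intergenic=n_inter / total,
        n_intronic=n_intron,
        prop_intronic=n_intron / total,
        n_genes_hit=len(genes_hit),
        n_cds=n_cds,
    )
    return summary, labels


# ---------------------------------------------------------------------------
# density tracks


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _covered_in(merged: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in merged)


def density_tracks(
    numts: Sequence,
    tes: Sequence[TEAnnotation],
    scaffold_lengths: Mapping[str, int],
    window: int = 50_000,
    step: int | None = None,
) -> list[DensityWindow]:
    """NUMT and TE coverage in ``window``-bp tiles over every scaffold that
    contains at least one NUMT.

    Windows are non-overlapping by default (``step = window``); the last
    window of a scaffold is truncated.  Overlapping annotations are flattened
    before computing coverage, so every coverage lies in [0, 1].
    """
    step = step or window
    numt_ivs: dict[str, list[tuple[int, int]]] = {}
    for n in numts:
        scaf, s, e = _unit_coords(n)
        numt_ivs.setdefault(scaf, []).append((s, e))
    te_ivs: dict[str, list[tuple[int, int]]] = {}
    for t in tes:
        te_ivs.setdefault(t.scaffold, []).append(t.interval)

    out: list[DensityWindow] = []
    for scaf in sorted(numt_ivs):
        L = scaffold_lengths[scaf]
        mn = _merge_intervals(numt_ivs[scaf])
        mt = _merge_intervals(te_ivs.get(scaf, []))
        for w0 in range(0, L, step):
            w1 = min(w0 + window, L)
            wlen = w1 - w0
            out.append(
                DensityWindow(
                    scaffold=scaf,
                    window_interval=(w0, w1),
                    numt_coverage=_covered_in(mn, w0, w1) / wlen,
                    te_coverage=_covered_in(mt, w0, w1) / wlen,
                )
            )
            if w1 == L:
                break
    return out


def write_density_bed(path: str | Path, windows: Sequence[DensityWindow]) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.scaffold}\t{w.window_interval[0]}\t{w.window_interval[1]}\t"
                f"{w.numt_coverage:.4f}\t{w.te_coverage:.4f}\n"
            )


# ---------------------------------------------------------------------------
# TE vicinity


def te_vicinity(
    numts: Sequence,
    tes: Sequence[TEAnnotation],
    window: int = 5_000,
    clusters: Sequence | None = None,
) -> TEVicinity:
    """TE content of the ``window``-bp neighbourhood of each NUMT unit.

    Single NUMTs are flagged if any TE overlaps either flank ([start-window,
    start) or [end, end+window)).  Complex clusters are treated as one unit
    spanning their outermost member boundaries, and TEs inside the cluster
    also count.  The nearest TE is chosen by minimum edge distance to the
    unit body, ties broken by larger overlap with the searched regions, then
    by coordinate.
    """
    numts = list(numts)
    by_id = {getattr(n, "numt_id", f"_{i}"): n for i, n in enumerate(numts)}
    units: list[tuple[str, str, int, int, bool]] = []  # (unit_id, scaffold, start, end, is_cluster)
    in_cluster: set[str] = set()
    for c in clusters or []:
        members = [by_id[m] for m in c.member_ids]
        in_cluster.update(c.member_ids)
        starts = [m.nuc_interval[0] for m in members]
        ends = [m.nuc_interval[1] for m in members]
        units.append((c.cluster_id, members[0].scaffold, min(starts), max(ends), True))
    for nid, n in by_id.items():
        if nid not in in_cluster:
            scaf, s, e = _unit_coords(n)
            units.append((nid, scaf, s, e, False))

    te_by_scaf: dict[str, list[TEAnnotation]] = {}
    for t in sorted(tes, key=lambda t: (t.scaffold, t.interval)):
        te_by_scaf.setdefault(t.scaffold, []).append(t)

    rows = []
    for uid, scaf, s, e, is_cluster in units:
        if is_cluster:
            regions = [(s - window, e + window)]
        else:
            regions = [(s - window, s), (e, e + window)]
        best = None  # (distance, -overlap, start, te)
        for t in te_by_scaf.get(scaf, []):
            ts, te_ = t.interval
            ov = sum(max(0, min(te_, hi) - max(ts, lo)) for lo, hi in regions)
            if ov <= 0:
                continue
            if te_ <= s:
                dist = s - te_
            elif ts >= e:
                dist = ts - e
            else:
                dist = 0
            key = (dist, -ov, ts)
            if best is None or key < best[:3]:
                best = (dist, -ov, ts, t)
        rows.append(
            {
                "unit_id": uid,
                "scaffold": scaf,
                "start": s,
                "end": e,
                "is_cluster": is_cluster,
                "has_te": best is not None,
                "nearest_superfamily": best[3].superfamily if best else None,
                "nearest_distance": best[0] if best else None,
            }
        )
    table = pd.DataFrame(rows)
    n_units = len(units)
    prop = float(table["has_te"].mean()) if n_units else 0.0
    with_te = table[table["has_te"]]
    counts = with_te["nearest_superfamily"].value_counts()
    props = (counts / counts.sum()).to_dict() if len(with_te) else {}
    return TEVicinity(table=table, prop_with_te=prop, superfamily_props=props, n_units=n_units)


# ---------------------------------------------------------------------------
# annotation readers


def read_repeatmasker_out(path: str | Path) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, 15-column rows).

    Query coordinates (1-based inclusive) are converted to 0-based half-open;
    the class/family column is preserved verbatim.
    """
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 14:
                raise ValueError(f"line {lineno}: malformed RepeatMasker row")
            try:
                div = float(fields[1])
                qbeg = int(fields[5])
                qend = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed RepeatMasker row") from exc
            out.append(
                TEAnnotation(
                    scaffold=fields[4],
                    interval=(qbeg - 1, qend),
                    te_name=fields[9],
                    superfamily=fields[10],
                    divergence=div,
                )
            )
    return out


def _gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS rows) from a GFF3 file.

    Exon and CDS rows are attached to their gene via the Parent chain; an
    exon whose parent cannot be resolved raises an error.
    """
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    pending: list[tuple[int, str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF3 columns")
            scaf, _src, ftype, start, end, _score, strand, _phase, attrs = f
            iv = (int(start) - 1, int(end))
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene{lineno}")
                genes[gid] = {"scaffold": scaf, "interval": iv, "strand": strand,
                              "exons": [], "cds": []}
            elif ftype == "mRNA":
                parent_of[a.get("ID", f"mrna{lineno}")] = a.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                pending.append((lineno, ftype, a.get("Parent", ""), iv[0], iv[1]))
    out: list[GeneModel] = []
    for lineno, ftype, parent, s, e in pending:
        gid = parent if parent in genes else parent_of.get(parent)
        if gid is None or gid not in genes:
            raise ValueError(f"line {lineno}: orphan {ftype} (unresolved Parent {parent!r})")
        genes[gid]["exons" if ftype == "exon" else "cds"].append((s, e))
    for gid, g in genes.items():
        out.append(
            GeneModel(
                gene_id=gid,
                scaffold=g["scaffold"],
                gene_interval=g["interval"],
                strand=g["strand"],
                exon_intervals=tuple(sorted(g["exons"])),
                cds_intervals=tuple(sorted(g["cds"])),
            )
        )
    out.sort(key=lambda g: (g.scaffold, g.gene_interval))
    return out
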