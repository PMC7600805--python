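"""Seed-and-extend search for mitochondrial homology in a nuclear genome.

The scanner finds exact k-mer seeds shared between the mitochondrial query
and each nuclear scaffold (both strands), extends them with affine-gap
x-drop dynamic programming, and scores significance with the Karlin-Altschul
formula E = K * m * n * exp(-lambda * S).  The same hit model can be loaded
from standard BLAST ``-outfmt 6`` tabular output, so the downstream
classification and context analyses run identically on hits produced by
blastn.

All internal coordinates are 0-based half-open; writers emit 1-based
inclusive coordinates where a format requires it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._align import banded_global_stats, encode, revcomp_codes, xdrop_extend

__all__ = [
    "SearchParams",
    "AlignmentHit",
    "scan_numts",
    "evalue",
    "bitscore",
    "filter_hits",
    "read_blast_tab",
    "read_fasta",
    "write_fasta",
    "write_hits",
]


@dataclass(frozen=True)
class SearchParams:
    """Scoring and significance parameters for the NUMT scan.

    Defaults follow megablast-style scoring (+1/-2, gap 5+2L) with the
    Karlin-Altschul parameters lambda=1.28, kappa=0.46 appropriate for that
    scheme.  ``search_m``/``search_n`` are the query (mitochondrial) length
    and total nuclear length; when left as None they are taken from the
    sequences passed to :func:`scan_numts`.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    kappa: float = 0.46
    xdrop: int = 20
    evalue_max: float = 1e-4
    min_len: int = 50
    report_evalue_max: float = 10.0
    search_m: int | None = None
    search_n: int | None = None

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between the mitochondrial genome and a scaffold.

    ``strand`` is the orientation of the nuclear segment relative to the
    mitochondrial forward strand; ``mito_interval`` is always given on the
    mitochondrial forward strand.  ``mito_terminal`` flags hits touching
    either end of the (linearised) mitochondrial sequence, where a
    circular-origin-spanning NUMT would be truncated.
    """

    scaffold: str
    nuc_interval: tuple[int, int]
    strand: str
    mito_interval: tuple[int, int]
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    aln_len: int
    mito_terminal: bool = False

    @property
    def nuc_len(self) -> int:
        return self.nuc_interval[1] - self.nuc_interval[0]

    @property
    def mito_len(self) -> int:
        return self.mito_interval[1] - self.mito_interval[0]


def evalue(raw_score: float, params: SearchParams) -> float:
    """Karlin-Altschul expected number of chance alignments scoring >= S.

    E = K * m * n * exp(-lambda * S), strictly decreasing in S.  Uses the
    raw search-space product m*n with no edge correction.
    """
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    if params.search_m is None or params.search_n is None:
        raise ValueError("search_m and search_n must be set to compute E-values")
    return params.kappa * params.search_m * params.search_n * math.exp(-params.lam * raw_score)


def bitscore(raw_score: float, params: SearchParams) -> float:
    """Bit score (lambda*S - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.kappa)) / math.log(2.0)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered dict of upper-case sequences.

    IUPAC ambiguity codes are tolerated on input; anything outside ACGT is
    treated as N by the scanner.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _kmer_hash(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-mer; returns (hashes, valid mask). N invalidates."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    hashes = np.zeros(n, dtype=np.int64)
    for t in range(k):
        hashes *= 4
        hashes += codes[t : t + n]
    bad = np.zeros(len(codes) + 1, dtype=np.int64)
    np.cumsum(codes >= 4, out=bad[1:])
    valid = (bad[k:] - bad[:-k]) == 0
    return hashes, valid


class _MitoIndex:
    def __init__(self, mito_codes: np.ndarray, k: int):
        hashes, valid = _kmer_hash(mito_codes, k)
        pos = np.nonzero(valid)[0]
        h = hashes[pos]
        order = np.argsort(h, kind="stable")
        self.sorted_hashes = h[order]
        self.sorted_pos = pos[order].astype(np.int64)

    def lookup(self, query_hashes: np.ndarray, query_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, mito_pos) seed pairs; vectorised."""
        qpos = np.nonzero(query_valid)[0]
        qh = query_hashes[qpos]
        left = np.searchsorted(self.sorted_hashes, qh, side="left")
        right = np.searchsorted(self.sorted_hashes, qh, side="right")
        counts = right - left
        keep = counts > 0
        qpos, left, counts = qpos[keep], left[keep], counts[keep]
        if len(qpos) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        seed_q = np.repeat(qpos, counts)
        # expand [left, left+count) ranges
        total = counts.sum()
        idx = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts) + np.repeat(left, counts)
        seed_m = self.sorted_pos[idx]
        return seed_q.astype(np.int64), seed_m


class _SeedSkipIndex:
    """Rectangles of already-extended alignments, keyed by seed diagonal so
    membership checks stay O(1) per seed."""

    def __init__(self) -> None:
        self.by_diag: dict[int, list[tuple[int, int, int, int]]] = {}

    def add(self, ns: int, ne: int, ms: int, me: int, dmin: int, dmax: int) -> None:
        rect = (ns, ne, ms, me)
        for d in range(dmin, min(dmax, dmin + 64) + 1):
            self.by_diag.setdefault(d, []).append(rect)

    def contains(self, i: int, j: int, k: int) -> bool:
        for ns, ne, ms, me in self.by_diag.get(i - j, ()):
            if ns <= i and i + k <= ne and ms <= j and j + k <= me:
                return True
        return False


def _scan_one(
    scaf_codes: np.ndarray,
    mito_codes: np.ndarray,
    index: "_MitoIndex",
    params: SearchParams,
) -> list[tuple[int, int, int, int, int, int, int, int]]:
    """Scan one (already oriented) scaffold; returns raw hit tuples
    (ns, ne, ms, me, score, matches, mismatches, gaps)."""
    k = params.word_size
    go = -params.gap_open
    ge = -params.gap_extend
    drift = params.xdrop // ge + 8
    pad = params.xdrop // ge + 4
    la_total = len(scaf_codes)
    lb_total = len(mito_codes)

    hashes, valid = _kmer_hash(scaf_codes, k)
    seed_q, seed_m = index.lookup(hashes, valid)
    if len(seed_q) == 0:
        return []
    order = np.lexsort((seed_m, seed_q))
    seed_q, seed_m = seed_q[order], seed_m[order]

    skip_index = _SeedSkipIndex()
    results: dict[tuple[int, int, int, int], tuple] = {}

    for i, j in zip(seed_q.tolist(), seed_m.tolist()):
        if skip_index.contains(i, j, k):
            continue
        # left extension on reversed prefixes, capped to useful extent
        ext_a = min(i, j + drift)
        a_left = np.ascontiguousarray(scaf_codes[i - ext_a : i][::-1])
        b_left = np.ascontiguousarray(mito_codes[:j][::-1])
        sl, al, bl = xdrop_extend(a_left, b_left, params.match, params.mismatch, go, ge, params.xdrop)
        # right extension
        rem_b = lb_total - (j + k)
        ext_ar = min(la_total - (i + k), rem_b + drift)
        a_right = np.ascontiguousarray(scaf_codes[i + k : i + k + ext_ar])
        b_right = np.ascontiguousarray(mito_codes[j + k :])
        sr, ar, br = xdrop_extend(a_right, b_right, params.match, params.mismatch, go, ge, params.xdrop)

        ns, ne = i - al, i + k + ar
        ms, me = j - bl, j + k + br
        score = int(sl) + int(sr) + k * params.match
        key = (ns, ne, ms, me)
        if key in results:
            stats = results[key]
            dminh, dmaxh = stats[5], stats[6]
        else:
            sc2, mat, mis, gaps, dmin, dmax = banded_global_stats(
                np.ascontiguousarray(scaf_codes[ns:ne]),
                np.ascontiguousarray(mito_codes[ms:me]),
                params.match,
                params.mismatch,
                go,
                ge,
                pad,
            )
            if sc2 > score:
                score = int(sc2)
            dminh = int(dmin) + (ns - ms)
            dmaxh = int(dmax) + (ns - ms)
            results[key] = (score, int(mat), int(mis), int(gaps), key, dminh, dmaxh)
        skip_index.add(ns, ne, ms, me, dminh, dmaxh)

    out = []
    for score, mat, mis, gaps, key, _, _ in results.values():
        ns, ne, ms, me = key
        out.append((ns, ne, ms, me, score, mat, mis, gaps))
    return out


def scan_numts(
    mito: str,
    nuclear: Mapping[str, str],
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """Find mito-homologous segments in every nuclear scaffold, both strands.

    Every maximal-scoring local alignment seeded by an exact ``word_size``-mer
    is reported once, subject to the reporting cap ``report_evalue_max``
    (default E <= 10, as for blastn); hits overlapping another hit by more
    than half on both the nuclear and the mitochondrial axis keep only the
    best-scoring representative.  Non-overlapping hits are never merged.
    """
    params = params or SearchParams()
    if not mito:
        raise ValueError("empty mitochondrial sequence")
    if not nuclear or all(len(s) == 0 for s in nuclear.values()):
        raise ValueError("empty nuclear genome")
    if params.word_size > len(mito):
        raise ValueError("word_size exceeds mitochondrial length")

    mito_codes = encode(mito)
    index = _MitoIndex(mito_codes, params.word_size)
    m = params.search_m if params.search_m is not None else len(mito)
    n = params.search_n if params.search_n is not None else sum(len(s) for s in nuclear.values())
    eff = replace(params, search_m=m, search_n=n)

    hits: list[AlignmentHit] = []
    for name, seq in nuclear.items():
        codes = encode(seq)
        L = len(seq)
        for strand in "+-":
            oriented = codes if strand == "+" else revcomp_codes(codes)
            for ns, ne, ms, me, score, mat, mis, gaps in _scan_one(oriented, mito_codes, index, eff):
                if evalue(score, eff) > eff.report_evalue_max:
                    continue
                if strand == "-":
                    ns, ne = L - ne, L - ns
                aln_len = mat + mis + gaps
                hits.append(
                    AlignmentHit(
                        scaffold=name,
                        nuc_interval=(ns, ne),
                        strand=strand,
                        mito_interval=(ms, me),
                        raw_score=score,
                        bitscore=bitscore(score, eff),
                        evalue=evalue(score, eff),
                        identity=mat / aln_len if aln_len else 0.0,
                        aln_len=aln_len,
                        mito_terminal=(ms == 0 or me == len(mito)),
                    )
                )
    return _dedup_overlapping(hits)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _dedup_overlapping(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Among hits >50%-overlapping on the nuclear axis that map to the same
    mitochondrial region, keep only the best-scoring one."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (-h.raw_score, h.scaffold, h.nuc_interval)):
        redundant = False
        for g in kept:
            if g.scaffold != h.scaffold:
                continue
            ov_n = _overlap(g.nuc_interval, h.nuc_interval)
            ov_m = _overlap(g.mito_interval, h.mito_interval)
            if (
                ov_n > 0.5 * min(h.nuc_len, g.nuc_len)
                and ov_m > 0.5 * min(h.mito_len, g.mito_len)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.scaffold, h.nuc_interval, h.mito_interval, h.strand))
    return kept


def filter_hits(hits: Iterable[AlignmentHit], params: SearchParams | None = None) -> list[AlignmentHit]:
    """Apply the significance and length filters: E < evalue_max and nuclear
    segment length >= min_len.  Output is stably ordered by (scaffold, start)."""
    params = params or SearchParams()
    kept = [h for h in hits if h.evalue < params.evalue_max and h.nuc_len >= params.min_len]
    kept.sort(key=lambda h: (h.scaffold, h.nuc_interval[0], h.nuc_interval[1]))
    return kept


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Load hits from BLAST ``-outfmt 6`` (12-column tabular) output.

    The mitochondrial genome is assumed to be the query.  Subject coordinates
    with start > end encode a minus-strand hit; 1-based inclusive coordinates
    are converted to 0-based half-open, and percent identity to a fraction.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: expected 12 tab-separated columns")
            try:
                (_q, sseqid, pident, length, _mm, _go, qstart, qend, sstart, send, ev, bs) = fields[:12]
                qs, qe, ss, se = int(qstart), int(qend), int(sstart), int(send)
                pid, length, ev, bs = float(pident), int(length), float(ev), float(bs)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed BLAST tabular row") from exc
            if ss <= se:
                strand = "+"
                nuc = (ss - 1, se)
            else:
                strand = "-"
                nuc = (se - 1, ss)
            hits.append(
                AlignmentHit(
                    scaffold=sseqid,
                    nuc_interval=nuc,
                    strand=strand,
                    mito_interval=(qs - 1, qe),
                    raw_score=0,
                    bitscore=bs,
                    evalue=ev,
                    identity=pid / 100.0,
                    aln_len=length,
                )
            )
    return hits


def write_hits(bed_path: str | Path, tsv_path: str | Path, hits: Sequence[AlignmentHit]) -> None:
    """Write hits as BED6 plus a companion TSV with mito coords, identity, E."""
    with open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        tsv.write("numt_id\tscaffold\tstart\tend\tstrand\tmito_start\tmito_end\tidentity\tevalue\tbitscore\n")
        for i, h in enumerate(hits, 1):
            nid = f"NUMT_{i:05d}"
            bed.write(
                f"{h.scaffold}\t{h.nuc_interval[0]}\t{h.nuc_interval[1]}\t{nid}\t{h.bitscore:.1f}\t{h.strand}\n"
            )
            tsv.write(
                f"{nid}\t{h.scaffold}\t{h.nuc_interval[0] + 1}\t{h.nuc_interval[1]}\t{h.strand}\t"
                f"{h.mito_interval[0] + 1}\t{h.mito_interval[1]}\t{h.identity:.4f}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )
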