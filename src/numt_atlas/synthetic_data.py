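"""Synthetic genomes with planted NUMTs, TEs and genes, plus a truth table.

The generator emulates the statistical structure the NUMT analyses assume:
an AT-rich ~15-16 kb (linearised) mitochondrial genome, a multi-scaffold
nuclear genome, planted insertion-type NUMTs with controlled divergence and
AT-biased insertion sites, duplicate-type NUMTs that carry nuclear flanking
DNA with them, complex NUMTs fragmented by TE-library insertions, and gene
models defining intergenic / intronic / CDS space.  Everything planted is
recorded in a truth table so recovery can be scored exactly.

Mutations are substitutions only by default (an indel-rate option exists but
defaults to 0), which keeps truth intervals exact.  All randomness flows
from the single ``seed`` in :class:`SimConfig`; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._align import decode, encode, revcomp_codes
from .genome_context import GeneModel, TEAnnotation
from .homology_search import write_fasta

__all__ = [
    "SimConfig",
    "TELibraryEntry",
    "TruthRecord",
    "SimResult",
    "simulate_genome",
    "write_fixture",
    "read_truth",
    "default_te_library",
    "write_gff",
    "write_repeatmasker_out",
    "write_truth",
]


@dataclass(frozen=True)
class TELibraryEntry:
    """One consensus repeat sequence available for planting."""

    name: str
    superfamily: str  # e.g. "LTR/Gypsy", "LINE/Jockey"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("TE sequence must be a non-empty ACGT string")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted NUMT (or NUMT fragment)."""

    numt_id: str
    scaffold: str
    nuc_interval: tuple[int, int]
    strand: str
    mito_interval: tuple[int, int]
    true_type: str  # insertion | duplicate
    family_id: str | None
    cluster_id: str | None
    divergence: float


@dataclass
class SimConfig:
    """Study conditions for one simulated genome.

    ``divergence_dist`` names the per-NUMT substitution rate distribution:
    ``("uniform", lo, hi)`` or ``("fixed", d)``; rates are per site in
    [0, 0.35].  ``at_site_bias`` >= 0 is the exponent applied to the local
    AT fraction (20 bp around a candidate site) when weighting insertion
    sites; 0 means uniform placement.  Duplicate events copy an existing
    planted NUMT together with ``dup_flank_carry`` bp of its nuclear flanks
    and re-insert the block elsewhere with ``dup_extra_divergence`` further
    substitutions.  Complex events split one planted NUMT with TE-library
    sequences so the fragments keep order and strand.
    """

    seed: int = 0
    mito_length: int = 15_800
    mito_at: float = 0.78
    n_scaffolds: int = 4
    scaffold_lengths: tuple[int, ...] | None = None  # default 500 kb each
    nuclear_at: float = 0.65
    n_insertions: int = 60
    numt_length_range: tuple[int, int] = (100, 3_000)
    divergence_dist: tuple = ("uniform", 0.0, 0.2)
    at_site_bias: float = 5.0
    n_duplications: int = 15
    dup_flank_carry: int = 1_000
    dup_extra_divergence: float = 0.02
    n_complex: int = 8
    complex_length_range: tuple[int, int] = (1_500, 6_000)
    complex_fragments: tuple[int, int] = (2, 4)
    te_library: tuple[TELibraryEntry, ...] | None = None
    n_te_background: int = 80
    n_genes: int = 40
    indel_rate: float = 0.0
    allow_exon_insertion: bool = False
    min_site_gap: int = 2_500

    def resolved_lengths(self) -> tuple[int, ...]:
        if self.scaffold_lengths is not None:
            return tuple(self.scaffold_lengths)
        return tuple([500_000] * self.n_scaffolds)

    def validate(self, te_library: Sequence[TELibraryEntry]) -> None:
        counts = (self.n_scaffolds, self.n_insertions, self.n_duplications,
                  self.n_complex, self.n_te_background, self.n_genes)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for f in (self.mito_at, self.nuclear_at, self.dup_extra_divergence):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.at_site_bias < 0:
            raise ValueError("at_site_bias must be >= 0")
        max_te = max((len(t.sequence) for t in te_library), default=0)
        max_feature = max(
            self.numt_length_range[1],
            self.numt_length_range[1] + 2 * self.dup_flank_carry,
            self.complex_length_range[1] + (self.complex_fragments[1] - 1) * max_te,
        )
        if min(self.resolved_lengths()) <= 2 * max_feature:
            raise ValueError("scaffolds too small: must exceed twice the largest planted feature")


@dataclass
class SimResult:
    mito: str
    nuclear: dict[str, str]
    truth: list[TruthRecord]
    te_annotations: list[TEAnnotation]
    genes: list[GeneModel]
    config: SimConfig


# ---------------------------------------------------------------------------
# primitives


def _random_codes(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate(codes: np.ndarray, d: float, rng: np.random.Generator, indel_rate: float = 0.0) -> np.ndarray:
    """Substitute each site with probability d (always to a different base)."""
    out = codes.copy()
    if d > 0:
        mask = (rng.random(len(out)) < d) & (out < 4)
        if mask.any():
            out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    if indel_rate > 0:
        keep = rng.random(len(out)) >= indel_rate / 2
        ins_at = np.nonzero(rng.random(len(out)) < indel_rate / 2)[0]
        pieces = []
        prev = 0
        for p in ins_at:
            pieces.append(out[prev : p + 1][keep[prev : p + 1]])
            pieces.append(rng.integers(0, 4, size=1).astype(np.uint8))
            prev = p + 1
        pieces.append(out[prev:][keep[prev:]])
        out = np.concatenate(pieces)
    return out


def _draw_divergence(dist: tuple, rng: np.random.Generator) -> float:
    name = dist[0]
    if name == "uniform":
        d = float(rng.uniform(dist[1], dist[2]))
    elif name == "fixed":
        d = float(dist[1])
    else:
        raise ValueError(f"unknown divergence distribution {name!r}")
    return float(np.clip(d, 0.0, 0.35))


def default_te_library(rng: np.random.Generator) -> tuple[TELibraryEntry, ...]:
    """A small repeat library dominated by Gypsy, mirroring the superfamily
    spectrum typical of TE-rich hymenopteran assemblies."""
    spec = [
        ("Gypsy-1", "LTR/Gypsy", 5_000),
        ("Gypsy-2", "LTR/Gypsy", 4_200),
        ("Jockey-1", "LINE/Jockey", 3_200),
        ("Mariner-1", "DNA/TcMar-Tc1", 1_300),
        ("RTE-1", "LINE/RTE", 2_500),
    ]
    return tuple(
        TELibraryEntry(name=n, superfamily=sf, sequence=decode(_random_codes(rng, L, 0.60)))
        for n, sf, L in spec
    )


_TE_WEIGHTS = np.array([0.30, 0.20, 0.25, 0.15, 0.10])


def _pick_te(library: Sequence[TELibraryEntry], rng: np.random.Generator) -> TELibraryEntry:
    if len(library) == len(_TE_WEIGHTS):
        return library[int(rng.choice(len(library), p=_TE_WEIGHTS))]
    return library[int(rng.integers(len(library)))]


# ---------------------------------------------------------------------------
# gene and TE placement (static coordinates, painted onto the background)


def _place_genes(
    rng: np.random.Generator,
    scaffold_names: Sequence[str],
    lengths: Sequence[int],
    n_genes: int,
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffold_names}
    lens = np.asarray(lengths, dtype=float)
    probs = lens / lens.sum()
    for gi in range(n_genes):
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(100, 401, size=n_exons)
        intron_lens = rng.integers(200, 1_501, size=n_exons - 1)
        glen = int(exon_lens.sum() + intron_lens.sum())
        placed = False
        for _ in range(1_000):
            si = int(rng.choice(len(scaffold_names), p=probs))
            scaf = scaffold_names[si]
            L = lengths[si]
            if L - glen - 400 <= 400:
                continue
            start = int(rng.integers(400, L - glen - 400))
            if any(start < e + 200 and s - 200 < start + glen for s, e in occupied[scaf]):
                continue
            occupied[scaf].append((start, start + glen))
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    scaffold=scaf,
                    gene_interval=(start, start + glen),
                    strand="+" if rng.random() < 0.5 else "-",
                    exon_intervals=tuple(exons),
                    cds_intervals=tuple(exons),
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError("could not place genes without overlap after 1000 attempts")
    genes.sort(key=lambda g: (g.scaffold, g.gene_interval))
    return genes


def _paint_background_tes(
    rng: np.random.Generator,
    backgrounds: dict[str, np.ndarray],
    genes: list[GeneModel],
    library: Sequence[TELibraryEntry],
    n_te: int,
) -> list[tuple[str, int, int, str, str, float]]:
    """Overwrite background sequence with TE copies (coordinates static).
    Returns (scaffold, start, end, name, superfamily, div%) tuples."""
    names = list(backgrounds)
    lens = np.array([len(backgrounds[s]) for s in names], dtype=float)
    probs = lens / lens.sum()
    exon_by_scaf: dict[str, list[tuple[int, int]]] = {s: [] for s in names}
    for g in genes:
        exon_by_scaf[g.scaffold].extend(g.exon_intervals)
    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in names}
    out = []
    for ti in range(n_te):
        entry = _pick_te(library, rng)
        tlen = len(entry.sequence)
        ok = False
        for _ in range(1_000):
            si = int(rng.choice(len(names), p=probs))
            scaf = names[si]
            L = len(backgrounds[scaf])
            if L - tlen - 400 <= 400:
                continue
            start = int(rng.integers(400, L - tlen - 400))
            end = start + tlen
            if any(start < e and s < end for s, e in placed[scaf]):
                continue
            if any(start < e and s < end for s, e in exon_by_scaf[scaf]):
                continue
            d = float(rng.uniform(0.0, 0.15))
            copy = _mutate(encode(entry.sequence), d, rng)
            if rng.random() < 0.5:
                copy = revcomp_codes(copy)
            backgrounds[scaf][start:end] = copy
            placed[scaf].append((start, end))
            out.append((scaf, start, end, entry.name, entry.superfamily, round(100 * d, 1)))
            ok = True
            break
        if not ok:
            raise ValueError("could not place background TEs after 1000 attempts")
    return out


# ---------------------------------------------------------------------------
# insertion-site sampling


def _site_weights(
    bg: np.ndarray,
    bias: float,
    margin: int,
    forbidden: list[tuple[int, int]],
) -> np.ndarray:
    at = ((bg == 0) | (bg == 3)).astype(np.float64)
    cs = np.zeros(len(at) + 1)
    np.cumsum(at, out=cs[1:])
    w = np.zeros(len(bg))
    lo, hi = 10, len(bg) - 10
    frac = (cs[20:] - cs[:-20]) / 20.0
    w[lo:hi] = frac[: hi - lo] ** bias
    w[:margin] = 0.0
    w[len(bg) - margin :] = 0.0
    for s, e in forbidden:
        w[max(0, s - 1) : e + 1] = 0.0
    return w


def _sample_sites(
    rng: np.random.Generator,
    weights: dict[str, np.ndarray],
    n_sites: int,
    min_gap: int,
) -> list[tuple[str, int]]:
    """Draw n_sites (scaffold, position) pairs with probability proportional
    to the site weights, enforcing a minimum pairwise separation."""
    if n_sites == 0:
        return []
    names = list(weights)
    cums = {s: np.cumsum(weights[s]) for s in names}
    totals = np.array([cums[s][-1] for s in names])
    if totals.sum() <= 0:
        raise ValueError("no candidate insertion sites with positive weight")
    probs = totals / totals.sum()
    chosen: dict[str, list[int]] = {s: [] for s in names}
    sites: list[tuple[str, int]] = []
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 1_000 * n_sites:
            raise ValueError("could not place features without overlap after 1000 attempts")
        si = int(rng.choice(len(names), p=probs))
        scaf = names[si]
        u = rng.uniform(0, totals[si])
        pos = int(np.searchsorted(cums[scaf], u, side="right"))
        lst = chosen[scaf]
        k = bisect.bisect_left(lst, pos)
        if k > 0 and pos - lst[k - 1] < min_gap:
            continue
        if k < len(lst) and lst[k] - pos < min_gap:
            continue
        bisect.insort(lst, pos)
        sites.append((scaf, pos))
    return sites


# ---------------------------------------------------------------------------
# the simulator


@dataclass
class _Block:
    scaffold: str
    point: int
    codes: np.ndarray
    # per planted fragment: (offset_in_block, length, strand, mito_interval,
    #                        true_type, family_key, cluster_key, divergence)
    fragments: list[tuple]
    # interior TEs: (offset_in_block, length, name, superfamily, div%)
    tes: list[tuple]


def simulate_genome(config: SimConfig) -> SimResult:
    """Generate the synthetic genome described by ``config``.

    Deterministic given the seed.  Raises ValueError for configs whose
    features cannot be placed without overlap (scaffolds too small).
    """
    rng = np.random.default_rng(config.seed)
    library = config.te_library if config.te_library is not None else default_te_library(rng)
    config.validate(library)

    lengths = config.resolved_lengths()
    names = [f"scaffold_{i + 1}" for i in range(len(lengths))]
    mito_codes = _random_codes(rng, config.mito_length, config.mito_at)
    backgrounds = {n: _random_codes(rng, L, config.nuclear_at) for n, L in zip(names, lengths)}

    genes = _place_genes(rng, names, lengths, config.n_genes)
    te_rows = _paint_background_tes(rng, backgrounds, genes, library, config.n_te_background)

    # candidate insertion sites, AT-biased, avoiding exons / painted TEs
    margin = max(1_500, config.dup_flank_carry + 100)
    forbidden: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    if not config.allow_exon_insertion:
        for g in genes:
            forbidden[g.scaffold].extend(g.exon_intervals)
    for scaf, s, e, *_ in te_rows:
        forbidden[scaf].append((s, e))
    weights = {
        n: _site_weights(backgrounds[n], config.at_site_bias, margin, forbidden[n]) for n in names
    }
    n_events = config.n_insertions + config.n_duplications + config.n_complex
    sites = _sample_sites(rng, weights, n_events, config.min_site_gap)

    blocks: list[_Block] = []
    lmin, lmax = config.numt_length_range

    # simple insertion-type NUMTs
    simple: list[_Block] = []
    for k in range(config.n_insertions):
        scaf, point = sites[k]
        L = int(rng.integers(lmin, lmax + 1))
        ms = int(rng.integers(0, config.mito_length - L + 1))
        d = _draw_divergence(config.divergence_dist, rng)
        seq = _mutate(mito_codes[ms : ms + L], d, rng, config.indel_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        codes = seq if strand == "+" else revcomp_codes(seq)
        blk = _Block(
            scaffold=scaf,
            point=point,
            codes=codes,
            fragments=[(0, len(codes), strand, (ms, ms + L), "insertion", None, None, d)],
            tes=[],
        )
        simple.append(blk)
        blocks.append(blk)

    # duplicate-type NUMTs: copy an existing insertion plus carried flanks
    if config.n_duplications and not simple:
        raise ValueError("duplications require at least one insertion-type NUMT")
    fam_of_source: dict[int, str] = {}
    for k in range(config.n_duplications):
        scaf, point = sites[config.n_insertions + k]
        src_idx = int(rng.integers(len(simple)))
        src = simple[src_idx]
        fam = fam_of_source.setdefault(src_idx, f"TFAM_{len(fam_of_source) + 1:03d}")
        carry = config.dup_flank_carry
        bg = backgrounds[src.scaffold]
        p = src.point
        block0 = np.concatenate([bg[p - carry : p], src.codes, bg[p : p + carry]])
        block = _mutate(block0, config.dup_extra_divergence, rng)
        (_, slen, sstrand, smito, _, _, _, sdiv) = src.fragments[0]
        off = carry
        strand = sstrand
        if rng.random() < 0.5:
            block = revcomp_codes(block)
            off = len(block) - (carry + slen)
            strand = "-" if sstrand == "+" else "+"
        d_eff = 1.0 - (1.0 - sdiv) * (1.0 - config.dup_extra_divergence)
        blocks.append(
            _Block(
                scaffold=scaf,
                point=point,
                codes=block,
                fragments=[(off, slen, strand, smito, "duplicate", fam, None, d_eff)],
                tes=[],
            )
        )
        # mark the source as the family original
        f = src.fragments[0]
        src.fragments[0] = (f[0], f[1], f[2], f[3], f[4], fam, f[6], f[7])

    # complex NUMTs: one insertion fragmented by TE-library sequences
    cmin, cmax = config.complex_length_range
    fmin, fmax = config.complex_fragments
    for k in range(config.n_complex):
        scaf, point = sites[config.n_insertions + config.n_duplications + k]
        total = int(rng.integers(cmin, cmax + 1))
        ms = int(rng.integers(0, config.mito_length - total + 1))
        d = _draw_divergence(config.divergence_dist, rng)
        seg = _mutate(mito_codes[ms : ms + total], d, rng, config.indel_rate)
        nfrag = int(rng.integers(fmin, fmax + 1))
        # cut the segment into nfrag pieces, each at least 300 bp
        while True:
            cuts = np.sort(rng.integers(300, total - 300 + 1, size=nfrag - 1))
            if nfrag == 1 or (np.diff(np.r_[0, cuts, total]) >= 300).all():
                break
        bounds = np.r_[0, cuts, total]
        cluster = f"TCC_{k + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        pieces: list[np.ndarray] = []
        frag_info: list[tuple] = []  # forward-block offsets
        te_info: list[tuple] = []
        pos = 0
        for fi in range(nfrag):
            a, b = int(bounds[fi]), int(bounds[fi + 1])
            pieces.append(seg[a:b])
            frag_info.append((pos, b - a, (ms + a, ms + b)))
            pos += b - a
            if fi < nfrag - 1:
                entry = _pick_te(library, rng)
                dt = float(rng.uniform(0.0, 0.15))
                tec = _mutate(encode(entry.sequence), dt, rng)
                pieces.append(tec)
                te_info.append((pos, len(tec), entry.name, entry.superfamily, round(100 * dt, 1)))
                pos += len(tec)
        block = np.concatenate(pieces)
        if strand == "-":
            block = revcomp_codes(block)
            Lb = len(block)
            frag_info = [(Lb - (o + l), l, mi) for o, l, mi in frag_info]
            te_info = [(Lb - (o + l), l, n_, sf, dv) for o, l, n_, sf, dv in te_info]
        blocks.append(
            _Block(
                scaffold=scaf,
                point=point,
                codes=block,
                fragments=[(o, l, strand, mi, "insertion", None, cluster, d) for o, l, mi in frag_info],
                tes=te_info,
            )
        )

    # assembly: splice blocks into the backgrounds
    nuclear: dict[str, str] = {}
    truth: list[TruthRecord] = []
    te_annotations: list[TEAnnotation] = []
    remap: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    truth_entries: list[tuple] = []  # gather, then number in coordinate order
    for scaf in names:
        bg = backgrounds[scaf]
        sblocks = sorted((b for b in blocks if b.scaffold == scaf), key=lambda b: b.point)
        pieces = []
        prev = 0
        offset = 0
        pts = []
        offs = []
        for b in sblocks:
            pieces.append(bg[prev : b.point])
            pieces.append(b.codes)
            start = b.point + offset
            for o, l, strand, mito_iv, ttype, fam, clus, d in b.fragments:
                truth_entries.append((scaf, start + o, start + o + l, strand, mito_iv, ttype, fam, clus, d))
            for o, l, n_, sf, dv in b.tes:
                te_annotations.append(
                    TEAnnotation(scaffold=scaf, interval=(start + o, start + o + l),
                                 te_name=n_, superfamily=sf, divergence=dv)
                )
            pts.append(b.point)
            offset += len(b.codes)
            offs.append(offset)
            prev = b.point
        pieces.append(bg[prev:])
        nuclear[scaf] = decode(np.concatenate(pieces) if len(pieces) > 1 else bg)
        remap[scaf] = (np.asarray(pts, dtype=np.int64), np.asarray(offs, dtype=np.int64))

    def _shift(scaf: str, pos: int, is_end: bool) -> int:
        pts, offs = remap[scaf]
        if len(pts) == 0:
            return pos
        k = np.searchsorted(pts, pos, side="left" if is_end else "right")
        return pos + (int(offs[k - 1]) if k > 0 else 0)

    genes_out: list[GeneModel] = []
    for g in genes:
        gi = (_shift(g.scaffold, g.gene_interval[0], False), _shift(g.scaffold, g.gene_interval[1], True))
        genes_out.append(
            replace(
                g,
                gene_interval=gi,
                exon_intervals=tuple(
                    (_shift(g.scaffold, s, False), _shift(g.scaffold, e, True)) for s, e in g.exon_intervals
                ),
                cds_intervals=tuple(
                    (_shift(g.scaffold, s, False), _shift(g.scaffold, e, True)) for s, e in g.cds_intervals
                ),
            )
        )

    for scaf, s, e, n_, sf, dv in te_rows:
        te_annotations.append(
            TEAnnotation(scaffold=scaf, interval=(_shift(scaf, s, False), _shift(scaf, e, True)),
                         te_name=n_, superfamily=sf, divergence=dv)
        )
    te_annotations.sort(key=lambda t: (t.scaffold, t.interval))

    truth_entries.sort(key=lambda t: (t[0], t[1]))
    for i, (scaf, s, e, strand, mito_iv, ttype, fam, clus, d) in enumerate(truth_entries, 1):
        truth.append(
            TruthRecord(
                numt_id=f"T{i:04d}",
                scaffold=scaf,
                nuc_interval=(s, e),
                strand=strand,
                mito_interval=mito_iv,
                true_type=ttype,
                family_id=fam,
                cluster_id=clus,
                divergence=d,
            )
        )

    return SimResult(
        mito=decode(mito_codes),
        nuclear=nuclear,
        truth=truth,
        te_annotations=te_annotations,
        genes=genes_out,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture writers and readers


def write_gff(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """GFF3 writer (gene/mRNA/exon/CDS, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.gene_interval)):
            s, e = g.gene_interval
            fh.write(f"{g.scaffold}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.scaffold}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
            for xs, xe in g.exon_intervals:
                fh.write(f"{g.scaffold}\tsim\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\tParent={tid}\n")
            for cs, ce in g.cds_intervals:
                fh.write(f"{g.scaffold}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\tParent={tid}\n")


def write_repeatmasker_out(
    path: str | Path, tes: Sequence[TEAnnotation], scaffold_lengths: Mapping[str, int]
) -> None:
    """RepeatMasker ``.out`` dialect: 3 header lines, 15 columns, 1-based."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query              matching"
            "  repeat         position in repeat\n"
            "score   div. del. ins.  sequence   begin  end          (left)     repeat"
            "         class/family   begin  end    (left)  ID\n\n"
        )
        for i, t in enumerate(sorted(tes, key=lambda t: (t.scaffold, t.interval)), 1):
            s, e = t.interval
            left = scaffold_lengths[t.scaffold] - e
            div = 0.0 if t.divergence is None else t.divergence
            tlen = e - s
            fh.write(
                f"{1000:5d} {div:5.1f} {0.0:4.1f} {0.0:4.1f}  {t.scaffold} {s + 1} {e} ({left}) + "
                f"{t.te_name} {t.superfamily} 1 {tlen} (0) {i}\n"
            )


def write_truth(path: str | Path, truth: Sequence[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("numt_id\tscaffold\tstart\tend\tstrand\tmito_start\tmito_end\ttype\tfamily_id\tcluster_id\tdivergence\n")
        for t in truth:
            fh.write(
                f"{t.numt_id}\t{t.scaffold}\t{t.nuc_interval[0]}\t{t.nuc_interval[1]}\t{t.strand}\t"
                f"{t.mito_interval[0]}\t{t.mito_interval[1]}\t{t.true_type}\t"
                f"{t.family_id or '.'}\t{t.cluster_id or '.'}\t{t.divergence!r}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("numt_id"):
            raise ValueError("not a truth table")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    numt_id=f[0],
                    scaffold=f[1],
                    nuc_interval=(int(f[2]), int(f[3])),
                    strand=f[4],
                    mito_interval=(int(f[5]), int(f[6])),
                    true_type=f[7],
                    family_id=None if f[8] == "." else f[8],
                    cluster_id=None if f[9] == "." else f[9],
                    divergence=float(f[10]),
                )
            )
    return out


def write_fixture(outdir: str | Path, result: SimResult) -> dict[str, Path]:
    """Write the whole simulation as plain-text fixture files.

    Emits mito FASTA, nuclear multi-FASTA, genes GFF3, repeats in
    RepeatMasker ``.out`` dialect and the truth TSV; all of them round-trip
    through this package's readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mito": outdir / "mito.fasta",
        "nuclear": outdir / "nuclear.fasta",
        "genes": outdir / "genes.gff3",
        "repeats": outdir / "repeats.out",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["mito"], {"mito": result.mito})
    write_fasta(paths["nuclear"], result.nuclear)
    write_gff(paths["genes"], result.genes)
    write_repeatmasker_out(
        paths["repeats"], result.te_annotations, {k: len(v) for k, v in result.nuclear.items()}
    )
    write_truth(paths["truth"], result.truth)
    return paths
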