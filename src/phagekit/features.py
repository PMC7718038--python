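"""Sequence-level genome characterization.

GC content, restriction-site mapping and in-silico digestion (linear,
circular, and circularly-permuted virion pools), consensus sigma-70
promoter scanning (TTGACA -- spacer -- TATAAT), Shine-Dalgarno ribosome
binding sites (AGGAGG), RBS-gated ORF calling, and a rho-independent
terminator heuristic (GC-rich hairpin followed by a U-tract).

Coordinates are 1-based and inclusive on the forward axis throughout,
with a strand flag where relevant.  Circular topology is handled by
scanning the sequence extended with a prefix of length pattern-1 and
de-duplicating hits modulo the sequence length.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "NucleotideSequence",
    "RestrictionEnzyme",
    "BUILTIN_ENZYMES",
    "FragmentSet",
    "PromoterHit",
    "RbsSite",
    "OrfRecord",
    "TerminatorHit",
    "PermutedDigest",
    "reverse_complement",
    "gc_content",
    "find_recognition_sites",
    "digest",
    "simulate_permuted_digest",
    "scan_sigma70_promoters",
    "scan_rbs",
    "find_orfs",
    "scan_terminators",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence with an identifier and a topology flag."""

    id: str
    residues: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise InvalidInputError(f"sequence {self.id!r} is empty")
        if self.topology not in ("linear", "circular"):
            raise InvalidInputError(f"unknown topology {self.topology!r}")
        bad = set(residues) - set("ACGTN")
        if bad:
            raise InvalidInputError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_fraction(self) -> float:
        return self.residues.count("N") / len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.residues), self.topology)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Type II restriction enzyme: IUPAC recognition string and the
    top/bottom-strand cut offsets in bases from the recognition start."""

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise InvalidInputError("recognition site must be at least 4 bases")
        if not (0 <= self.cut_offset_top <= len(self.recognition)):
            raise InvalidInputError("cut_offset_top outside the recognition site")
        if not (0 <= self.cut_offset_bottom <= len(self.recognition)):
            raise InvalidInputError("cut_offset_bottom outside the recognition site")


#: Standard definitions of the enzymes used throughout; offsets give the
#: position of the phosphodiester cleavage on each strand, counted in
#: bases from the recognition-site start (SacI: GAGCT^C, ApaI: GGGCC^C,
#: XhoI: C^TCGAG).
BUILTIN_ENZYMES = {
    e.name: e
    for e in [
        RestrictionEnzyme("SacI", "GAGCTC", 5, 1),
        RestrictionEnzyme("ApaI", "GGGCCC", 5, 1),
        RestrictionEnzyme("XhoI", "CTCGAG", 1, 5),
        RestrictionEnzyme("EcoRI", "GAATTC", 1, 5),
        RestrictionEnzyme("BamHI", "GGATCC", 1, 5),
        RestrictionEnzyme("HindIII", "AAGCTT", 1, 5),
    ]
}


def get_enzyme(enzyme) -> RestrictionEnzyme:
    if isinstance(enzyme, RestrictionEnzyme):
        return enzyme
    try:
        return BUILTIN_ENZYMES[enzyme]
    except KeyError:
        raise InvalidInputError(
            f"unknown enzyme {enzyme!r}; built-ins: {sorted(BUILTIN_ENZYMES)}"
        ) from None


@dataclass(frozen=True)
class Fragment:
    start: int  # 1-based inclusive, forward axis
    end: int  # may wrap past the origin on circular molecules
    length: int


@dataclass
class FragmentSet:
    """Digestion product: cleavage coordinates and the resulting fragments.

    ``cut_positions`` are top-strand cleavage coordinates: the cut falls
    *after* the listed base.  On circular molecules with no cuts a single
    full-length fragment is returned with ``uncut=True``.
    """

    topology: str
    sequence_length: int
    cut_positions: list
    fragments: list
    uncut: bool = False

    @property
    def lengths(self) -> list:
        return [f.length for f in self.fragments]


def _atcg_counts(seq: str):
    c = Counter(seq)
    return c["A"], c["C"], c["G"], c["T"]


def gc_content(seq) -> float:
    """GC percentage, ``100 * (G+C) / (A+C+G+T)``.  Ambiguous N bases are
    excluded from the denominator; an all-N sequence is undefined."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    if not residues:
        raise InvalidInputError("empty sequence")
    a, c, g, t = _atcg_counts(residues)
    denom = a + c + g + t
    if denom == 0:
        raise InvalidInputError("GC content undefined: sequence contains no A/C/G/T")
    return 100.0 * (g + c) / denom


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise InvalidInputError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        exp = IUPAC[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def find_recognition_sites(seq, enzyme) -> list:
    """1-based start positions of every top-strand recognition-site match.

    Overlapping matches are all reported.  For the palindromic built-in
    enzymes each physical site appears exactly once.  Circular topology
    additionally checks windows spanning the origin.
    """
    enzyme = get_enzyme(enzyme)
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    pat = _iupac_regex(enzyme.recognition)
    text = seq.residues
    if seq.topology == "circular" and len(text) >= len(enzyme.recognition):
        text = text + text[: len(enzyme.recognition) - 1]
    positions = sorted(
        {(m.start() % len(seq)) + 1 for m in pat.finditer(text) if m.start() < len(seq)}
    )
    return positions


def cut_coordinates(seq, enzyme) -> list:
    """Top-strand cleavage coordinates: the cut falls after the returned
    base.  Derived from site starts plus the enzyme's top-strand offset,
    wrapped modulo the length on circular molecules."""
    enzyme = get_enzyme(enzyme)
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    length = len(seq)
    coords = []
    for site in find_recognition_sites(seq, enzyme):
        coord = site + enzyme.cut_offset_top - 1
        if seq.topology == "circular":
            coord = ((coord - 1) % length) + 1
        elif coord >= length:  # cut past the end of a linear molecule: no cleavage
            continue
        coords.append(coord)
    return sorted(set(coords))


def digest(seq, enzymes) -> FragmentSet:
    """Digest with one or more enzymes.

    Circular molecules yield one fragment per cut (arcs between
    successive cleavages); linear molecules yield cuts + 1 fragments
    including both ends.  Fragment lengths always sum to the sequence
    length.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    if isinstance(enzymes, (str, RestrictionEnzyme)):
        enzymes = [enzymes]
    if not enzymes:
        raise InvalidInputError("at least one enzyme is required")
    cuts = sorted({c for e in enzymes for c in cut_coordinates(seq, e)})
    length = len(seq)
    fragments = []
    if seq.topology == "circular":
        if not cuts:
            return FragmentSet("circular", length, [], [Fragment(1, length, length)], uncut=True)
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            frag_len = (nxt - c) % length or length
            start = ((c) % length) + 1
            end = ((c + frag_len - 1) % length) + 1
            fragments.append(Fragment(start, end, frag_len))
        return FragmentSet("circular", length, cuts, fragments)
    boundaries = [0] + [c for c in cuts if c < length] + [length]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b > a:
            fragments.append(Fragment(a + 1, b, b - a))
    return FragmentSet("linear", length, cuts, fragments)


@dataclass
class PermutedDigest:
    """Pooled digestion products of a circularly permuted virion population."""

    headful_length: int
    n_virions: int
    virion_starts: list
    per_virion_fragments: list  # list of lists of fragment lengths
    pooled_lengths: list  # flattened
    length_counts: Counter

    def histogram(self, bins=30):
        return np.histogram(self.pooled_lengths, bins=bins)


def simulate_permuted_digest(
    seq_length: int,
    pac_position: int,
    headful_length: int,
    n_virions: int,
    enzyme_cuts: Sequence[int],
) -> PermutedDigest:
    """Digest a headful-packaged virion pool in silico.

    Packaging starts at ``pac_position`` and each successive virion takes
    the next ``headful_length`` bases around the circle (terminal
    redundancy when headful exceeds the genome), so virion i is the linear
    arc starting at ``(pac + i * headful) mod L``.  Each virion is then
    digested linearly at the circle's cleavage coordinates
    (``enzyme_cuts``, cut after the listed base), and all fragment lengths
    are pooled.  Every virion's fragments sum to the headful length.
    """
    if n_virions < 1:
        raise InvalidInputError("n_virions must be >= 1")
    if headful_length < 1 or seq_length < 1:
        raise InvalidInputError("lengths must be positive")
    length = seq_length
    cuts = sorted({((c - 1) % length) + 1 for c in enzyme_cuts})
    starts = []
    per_virion = []
    pooled = []
    for i in range(n_virions):
        start = ((pac_position - 1 + i * headful_length) % length) + 1
        starts.append(start)
        # virion position v (1-based) maps to genome base ((start-1 + v-1) mod L)+1;
        # a circle cut after base c becomes a cut after virion position v when
        # genome(v) == c, for every wrap copy inside the headful
        internal = []
        for c in cuts:
            v = ((c - start) % length) + 1
            while v < headful_length:
                internal.append(v)
                v += length
        internal = sorted(set(internal))
        frags = []
        prev = 0
        for v in internal:
            frags.append(v - prev)
            prev = v
        frags.append(headful_length - prev)
        per_virion.append(frags)
        pooled.extend(frags)
    return PermutedDigest(
        headful_length=headful_length,
        n_virions=n_virions,
        virion_starts=starts,
        per_virion_fragments=per_virion,
        pooled_lengths=pooled,
        length_counts=Counter(pooled),
    )


# ---------------------------------------------------------------------------
# consensus motif scanning

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"
SHINE_DALGARNO = "AGGAGG"
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class PromoterHit:
    """A sigma-70 promoter consensus hit.

    ``start``/``end`` span the whole element on the forward axis;
    ``minus35_start``/``minus10_start`` give the forward-axis coordinate
    of the 5'-most base of each hexamer *read along the hit's strand*
    (for minus-strand hits these are the right edges on the forward axis).
    """

    strand: str
    start: int
    end: int
    minus35_start: int
    minus10_start: int
    spacer_len: int
    mismatches: int


def _mismatch_profile(encoded: np.ndarray, motif: str) -> np.ndarray:
    """mismatches[i] = Hamming distance between seq[i:i+len(motif)] and motif;
    N (encoded as 0) never matches."""
    n = len(encoded)
    m = len(motif)
    if n < m:
        return np.empty(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    codes = {"A": 1, "C": 2, "G": 3, "T": 4}
    for j, ch in enumerate(motif):
        out += (encoded[j : n - m + 1 + j] != codes[ch]).astype(np.int32)
    return out


def _encode(seq: str) -> np.ndarray:
    table = np.zeros(256, dtype=np.int8)
    for code, ch in enumerate("ACGT", start=1):
        table[ord(ch)] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_sigma70_promoters(
    seq,
    max_mismatch_total: int = 2,
    spacer_range=(17, 17),
    per_box_max: Optional[int] = None,
    both_strands: bool = True,
) -> list:
    """Scan for sigma-70 promoters: TTGACA, a spacer whose length lies in
    ``spacer_range`` (default exactly 17 nt), then TATAAT, with at most
    ``max_mismatch_total`` mismatches over both hexamers (optionally capped
    per box).  Both strands are scanned; overlapping hits are all reported,
    sorted by forward-axis position."""
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    smin, smax = spacer_range
    if smin > smax or smin < 0:
        raise InvalidInputError("invalid spacer_range")
    per_box = max_mismatch_total if per_box_max is None else per_box_max
    length = len(seq)
    hits = []
    strands = [("+", seq.residues)]
    if both_strands:
        strands.append(("-", reverse_complement(seq.residues)))
    for strand, text in strands:
        if seq.topology == "circular":
            text = text + text[: 12 + smax - 1]
        enc = _encode(text)
        mm35 = _mismatch_profile(enc, MINUS35)
        mm10 = _mismatch_profile(enc, MINUS10)
        for spacer in range(smin, smax + 1):
            span = 12 + spacer
            limit = min(len(mm35), len(mm10) - 6 - spacer)
            if limit <= 0:
                continue
            total = mm35[:limit] + mm10[6 + spacer : limit + 6 + spacer]
            ok = np.flatnonzero(
                (total <= max_mismatch_total)
                & (mm35[:limit] <= per_box)
                & (mm10[6 + spacer : limit + 6 + spacer] <= per_box)
            )
            for i in ok:
                i = int(i)
                if i >= length:  # circular junction duplicate
                    continue
                if strand == "+":
                    start = i + 1
                    end = i + span
                    m35 = start
                    m10 = start + 6 + spacer
                else:
                    # position in rc coordinates -> forward axis
                    end_f = length - i
                    start_f = length - (i + span) + 1
                    start, end = start_f, end_f
                    m35 = end_f
                    m10 = end_f - 6 - spacer
                if seq.topology == "circular":
                    start = ((start - 1) % length) + 1
                    end = ((end - 1) % length) + 1
                hits.append(
                    PromoterHit(
                        strand=strand,
                        start=start,
                        end=end,
                        minus35_start=m35,
                        minus10_start=m10,
                        spacer_len=spacer,
                        mismatches=int(total[i]),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.spacer_len))
    return hits


@dataclass(frozen=True)
class RbsSite:
    """A Shine-Dalgarno match upstream of a start codon."""

    motif_match: str
    match_len: int
    start: int  # forward-axis 1-based start of the match (leftmost base)
    end: int
    strand: str
    gap_to_start_codon: int


def _scan_rbs_plus(text: str, orf_start0: int, min_match_len: int, gap_range) -> Optional[tuple]:
    gmin, gmax = gap_range
    for match_len in range(len(SHINE_DALGARNO), min_match_len - 1, -1):
        for gap in range(gmin, gmax + 1):
            for offset in range(0, len(SHINE_DALGARNO) - match_len + 1):
                sub = SHINE_DALGARNO[offset : offset + match_len]
                s0 = orf_start0 - gap - match_len
                if s0 < 0:
                    continue  # window truncated at the sequence start
                if text[s0 : s0 + match_len] == sub:
                    return sub, match_len, s0, gap
    return None


def scan_rbs(
    seq,
    orf_start: int,
    strand: str = "+",
    min_match_len: int = 4,
    gap_range=(5, 9),
) -> Optional[RbsSite]:
    """Find the best Shine-Dalgarno (AGGAGG) match upstream of a start codon.

    The match must be a contiguous substring of AGGAGG of length >=
    ``min_match_len`` whose 3' end sits ``gap`` nucleotides upstream of the
    start codon with ``gap`` in ``gap_range`` (default 5-9 nt).  The best
    hit is the longest match, ties broken by the smallest gap.  ``orf_start``
    is the forward-axis coordinate of the start codon's 5' base on the given
    strand (for the minus strand, the rightmost base of the codon).
    Windows extending past the sequence start are truncated, not errors.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    length = len(seq)
    if strand == "+":
        found = _scan_rbs_plus(seq.residues, orf_start - 1, min_match_len, gap_range)
        if found is None:
            return None
        sub, match_len, s0, gap = found
        return RbsSite(sub, match_len, s0 + 1, s0 + match_len, "+", gap)
    if strand == "-":
        rc = reverse_complement(seq.residues)
        rc_start0 = length - orf_start  # 0-based position of the codon in rc coords
        found = _scan_rbs_plus(rc, rc_start0, min_match_len, gap_range)
        if found is None:
            return None
        sub, match_len, s0, gap = found
        # map rc interval [s0, s0+match_len) back to forward axis
        start_f = length - (s0 + match_len) + 1
        end_f = length - s0
        return RbsSite(sub, match_len, start_f, end_f, "-", gap)
    raise InvalidInputError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame from start codon to in-frame stop (inclusive).

    Coordinates are on the forward axis with ``start < end``; ``strand``
    tells the reading direction.  ``gene_call`` is True when the ORF is
    considered protein-coding, which (with RBS gating on) requires a
    Shine-Dalgarno site upstream of the start codon.
    """

    start: int
    end: int
    strand: str
    start_codon: str
    length_nt: int
    rbs: Optional[RbsSite]
    gene_call: bool


def _orfs_one_strand(text: str, min_length_nt: int, start_codons) -> list:
    """(start0, end0, codon) for each stop codon's longest-start ORF; 0-based
    half-open on the given strand's own coordinates."""
    out = []
    n = len(text)
    for frame in range(3):
        first_start = None
        pos = frame
        while pos + 3 <= n:
            codon = text[pos : pos + 3]
            if codon in STOP_CODONS:
                if first_start is not None:
                    length = pos + 3 - first_start
                    if length >= min_length_nt:
                        out.append((first_start, pos + 3, text[first_start : first_start + 3]))
                first_start = None
            elif first_start is None and codon in start_codons:
                first_start = pos
            pos += 3
    return out


def find_orfs(
    seq,
    min_length_nt: int = 90,
    start_codons=("ATG", "GTG", "TTG"),
    require_rbs: bool = True,
    min_match_len: int = 4,
    gap_range=(5, 9),
) -> list:
    """Enumerate complete ORFs on both strands (3 frames each).

    One ORF is reported per stop codon: the variant with the earliest
    in-frame start codon after the previous stop ("longest start"), so
    nested ORFs sharing a stop are not duplicated.  ``length_nt`` counts
    start through stop inclusive.  With ``require_rbs`` (default) an ORF is
    marked ``gene_call=True`` only when :func:`scan_rbs` finds a
    Shine-Dalgarno site upstream of its start codon.
    """
    if min_length_nt < 30:
        raise InvalidInputError("min_length_nt must be >= 30")
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    length = len(seq)
    records = []
    for strand in ("+", "-"):
        text = seq.residues if strand == "+" else reverse_complement(seq.residues)
        for s0, e0, codon in _orfs_one_strand(text, min_length_nt, start_codons):
            if strand == "+":
                start, end = s0 + 1, e0
                rbs_anchor = start
            else:
                start, end = length - e0 + 1, length - s0
                rbs_anchor = end
            rbs = scan_rbs(seq, rbs_anchor, strand, min_match_len, gap_range)
            gene_call = (rbs is not None) if require_rbs else True
            records.append(
                OrfRecord(
                    start=start,
                    end=end,
                    strand=strand,
                    start_codon=codon,
                    length_nt=e0 - s0,
                    rbs=rbs,
                    gene_call=gene_call,
                )
            )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


@dataclass(frozen=True)
class TerminatorHit:
    """A rho-independent terminator candidate: a perfect inverted-repeat
    stem, a short loop, and a downstream U-tract on the coding strand."""

    strand: str
    position: int  # forward-axis 1-based start of the hairpin (stem 5' arm)
    stem_len: int
    loop_len: int
    u_count: int
    score: float


def scan_terminators(
    seq,
    min_stem: int = 5,
    loop_range=(3, 10),
    tail_window: int = 8,
    min_u: int = 4,
    max_gap: int = 3,
) -> list:
    """Heuristic rho-independent terminator scan on both strands.

    A hit is a perfect inverted repeat (Watson-Crick pairs only) with stem
    length >= ``min_stem`` and loop length in ``loop_range``, followed
    within ``max_gap`` nt by a ``tail_window``-nt window containing at
    least ``min_u`` T residues on the coding strand.  Stems are extended
    maximally, so each (apex, loop) yields at most one hit.  The score is
    ``3*GC_pairs + 2*AT_pairs + u_count - loop_len``.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    length = len(seq)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    hits = []
    for strand in ("+", "-"):
        text = seq.residues if strand == "+" else reverse_complement(seq.residues)
        n = len(text)
        for loop_len in range(loop_range[0], loop_range[1] + 1):
            for a in range(1, n - loop_len):
                # count consecutive complementary pairs around loop [a, a+loop_len)
                k = 0
                while (
                    a - 1 - k >= 0
                    and a + loop_len + k < n
                    and comp.get(text[a - 1 - k]) == text[a + loop_len + k]
                ):
                    k += 1
                if k < min_stem:
                    continue
                stem_start = a - k
                stem_end = a + loop_len + k - 1  # 0-based inclusive
                gc_pairs = sum(
                    1 for j in range(k) if text[a - 1 - j] in "GC"
                )
                at_pairs = k - gc_pairs
                u_count = 0
                for gap in range(0, max_gap + 1):
                    w0 = stem_end + 1 + gap
                    window = text[w0 : w0 + tail_window]
                    if len(window) < min_u:
                        continue
                    u_count = max(u_count, window.count("T"))
                if u_count < min_u:
                    continue
                score = 3.0 * gc_pairs + 2.0 * at_pairs + u_count - loop_len
                pos0 = stem_start if strand == "+" else n - (stem_end + 1)
                hits.append(
                    TerminatorHit(
                        strand=strand,
                        position=pos0 + 1,
                        stem_len=k,
                        loop_len=loop_len,
                        u_count=u_count,
                        score=score,
                    )
                )
    hits.sort(key=lambda h: (h.position, h.strand, -h.score))
    return hits
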