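"""Random genomes with planted, ground-truthed features.

Generates an i.i.d. background sequence at a requested GC content and
writes exact feature motifs into it — sigma-70 promoter elements
(TTGACA + 17 nt spacer + TATAAT), Shine-Dalgarno/ORF cassettes
(AGGAGG + 5-9 nt spacer + ATG ... TAA), and restriction recognition
sites — returning the sequence together with a truth table for scanner
validation.  The background (and every redrawable random stretch inside
a planted feature) is kept free of accidental recognition sites for the
planted enzymes by rejection resampling, so site counts are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .features import (
    MINUS10,
    MINUS35,
    SHINE_DALGARNO,
    STOP_CODONS,
    NucleotideSequence,
    find_recognition_sites,
    get_enzyme,
    reverse_complement,
)

__all__ = ["SyntheticGenomeSpec", "generate_genome"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for a synthetic genome.

    Feature positions are 1-based forward-axis coordinates:

    * promoters: ``(position, strand)`` — leftmost base of the 29-nt
      element (−35 box, 17-nt spacer, −10 box).
    * rbs_orfs: ``(position, strand, orf_length)`` — ``position`` is the
      5' base of the start codon on the given strand (for ``-`` the
      rightmost forward-axis base); ``orf_length`` counts start through
      stop codon and must be a multiple of 3, at least 9.
    * cut_sites: ``(enzyme_name, position)`` — recognition-site start.

    Planted features (including the RBS cassette upstream of each ORF)
    must not overlap.
    """

    length: int
    gc_target: float = 0.5
    planted_promoters: Sequence = ()
    planted_rbs_orfs: Sequence = ()
    planted_cut_sites: Sequence = ()
    topology: str = "linear"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidInputError("length must be positive")
        if not (0.0 < self.gc_target < 1.0):
            raise InvalidInputError("gc_target must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticGenomeSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"length", "gc_target", "promoters", "rbs_orfs", "cut_sites", "topology", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown keys in genome recipe: {sorted(unknown)}")
        return cls(
            length=int(raw["length"]),
            gc_target=float(raw.get("gc_target", 0.5)),
            planted_promoters=[tuple(x) for x in raw.get("promoters", [])],
            planted_rbs_orfs=[tuple(x) for x in raw.get("rbs_orfs", [])],
            planted_cut_sites=[tuple(x) for x in raw.get("cut_sites", [])],
            topology=raw.get("topology", "linear"),
            seed=raw.get("seed"),
        )


def _draw_bases(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _random_nonstop_codons(rng, n_codons, gc, forbidden_patterns, max_tries=200):
    for _ in range(max_tries):
        codons = []
        while len(codons) < n_codons:
            codon = "".join(_draw_bases(rng, 3, gc))
            if codon not in STOP_CODONS:
                codons.append(codon)
        text = "".join(codons)
        if not any(p in text for p in forbidden_patterns):
            return text
    raise InvalidInputError("could not draw enzyme-site-free ORF interior")


def _check_interval(intervals, start, end, name):
    for s, e, other in intervals:
        if start <= e and s <= end:
            raise InvalidInputError(
                f"planted feature collision: {name} [{start},{end}] overlaps {other} [{s},{e}]"
            )
    intervals.append((start, end, name))


def generate_genome(spec: SyntheticGenomeSpec):
    """Generate the sequence and its truth table.

    Returns
    -------
    (NucleotideSequence, pandas.DataFrame)
        The truth table has one row per planted feature (promoters are one
        row; each RBS-ORF cassette contributes a CDS row and an RBS row;
        cut sites carry their cleavage coordinate in ``note``), with
        columns ``feature_type, name, start, end, strand, note``.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.length
    enzymes = [get_enzyme(name) for name, _ in spec.planted_cut_sites]
    forbidden = sorted({e.recognition for e in enzymes})

    seq = _draw_bases(rng, length, spec.gc_target)
    fixed = np.zeros(length, dtype=bool)  # bases that are part of a planted motif
    intervals: list = []
    truth_rows = []

    def put(start1, text, name):
        start0 = start1 - 1
        end0 = start0 + len(text)
        if start0 < 0 or end0 > length:
            raise InvalidInputError(f"feature {name} does not fit inside the genome")
        seq[start0:end0] = list(text)
        fixed[start0:end0] = True

    # promoters -------------------------------------------------------------
    for idx, (pos, strand) in enumerate(spec.planted_promoters):
        name = f"promoter_{idx}"
        start, end = pos, pos + 28
        _check_interval(intervals, start, end, name)
        for _ in range(100):
            spacer = "".join(_draw_bases(rng, 17, spec.gc_target))
            element = MINUS35 + spacer + MINUS10
            if not any(p in element for p in forbidden):
                break
        else:
            raise InvalidInputError("could not draw enzyme-free promoter spacer")
        put(start, element if strand == "+" else reverse_complement(element), name)
        truth_rows.append(("promoter", name, start, end, strand, "spacer_len=17"))

    # RBS-gated ORF cassettes ------------------------------------------------
    for idx, (pos, strand, orf_length) in enumerate(spec.planted_rbs_orfs):
        name = f"orf_{idx}"
        if orf_length % 3 != 0 or orf_length < 9:
            raise InvalidInputError(f"{name}: orf_length must be a multiple of 3, >= 9")
        gap = int(rng.integers(5, 10))
        n_interior = orf_length // 3 - 2
        interior = _random_nonstop_codons(rng, n_interior, spec.gc_target, forbidden)
        orf = "ATG" + interior + "TAA"
        # spacer between AGGAGG and the start codon, with an in-frame stop
        # just before the start so the planted ATG is the longest start
        for _ in range(100):
            spacer = list("".join(_draw_bases(rng, gap, spec.gc_target)))
            spacer[gap - 3 : gap] = list("TAA")
            cassette = SHINE_DALGARNO + "".join(spacer) + orf
            if not any(p in cassette for p in forbidden):
                break
        else:
            raise InvalidInputError("could not draw enzyme-free RBS cassette")
        if strand == "+":
            orf_start, orf_end = pos, pos + orf_length - 1
            cass_start = pos - gap - 6
            _check_interval(intervals, cass_start, orf_end, name)
            put(cass_start, cassette, name)
            rbs_start, rbs_end = cass_start, cass_start + 5
        else:
            orf_start, orf_end = pos - orf_length + 1, pos
            cass_end = pos + gap + 6
            _check_interval(intervals, orf_start, cass_end, name)
            put(orf_start, reverse_complement(cassette), name)
            rbs_start, rbs_end = cass_end - 5, cass_end
        truth_rows.append(
            ("CDS", name, orf_start, orf_end, strand, f"length_nt={orf_length}")
        )
        truth_rows.append(
            ("RBS", f"rbs_{idx}", rbs_start, rbs_end, strand, f"gap={gap}")
        )

    # restriction sites -------------------------------------------------------
    for idx, (enzyme_name, pos) in enumerate(spec.planted_cut_sites):
        enzyme = get_enzyme(enzyme_name)
        name = f"site_{enzyme.name}_{idx}"
        end = pos + len(enzyme.recognition) - 1
        _check_interval(intervals, pos, end, name)
        put(pos, enzyme.recognition, name)
        cut = pos + enzyme.cut_offset_top - 1
        truth_rows.append(
            ("restriction_site", name, pos, end, "+", f"enzyme={enzyme.name};cut_after={cut}")
        )

    # rejection: purge accidental recognition sites for the planted enzymes ---
    planted_site_starts = {
        (row[5].split(";")[0].split("=")[1], row[2])
        for row in truth_rows
        if row[0] == "restriction_site"
    }
    for _ in range(200):
        record = NucleotideSequence("synthetic", "".join(seq), spec.topology)
        accidental = []
        for enzyme in enzymes:
            for site in find_recognition_sites(record, enzyme):
                if (enzyme.name, site) not in planted_site_starts:
                    accidental.append((enzyme, site))
        if not accidental:
            break
        for enzyme, site in accidental:
            span = np.arange(site - 1, site - 1 + len(enzyme.recognition)) % length
            redraw = span[~fixed[span]]
            if len(redraw) == 0:
                raise InvalidInputError(
                    f"accidental {enzyme.name} site at {site} lies entirely inside "
                    "planted features; adjust the spec"
                )
            seq[redraw] = _draw_bases(rng, len(redraw), spec.gc_target)
    else:
        raise InvalidInputError("rejection sampling failed to remove accidental sites")

    record = NucleotideSequence("synthetic", "".join(seq), spec.topology)
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_type", "name", "start", "end", "strand", "note"],
    )
    return record, truth
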