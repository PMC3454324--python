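"""Scanning aligned regions for motif hits with a cross-species filter.

Regions come as per-region multiple alignments (reference species first).
PWM hits above a calibrated threshold, and RCGTG consensus matches, are
kept as "conserved" only when enough species carry the identical base at
every informative motif position (positions whose information content
exceeds the IC-mask cutoff; all positions for the RCGTG consensus).
Gaps and unknown bases count as mismatches, and a configurable set of
species (by default the reference and mouse) must be among the matches.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pwm import PWM, encode

RCGTG_ID = "RCGTG"
_RCGTG_FWD = re.compile(r"(?=([AG]CGTG))")
_RCGTG_REV = re.compile(r"(?=(CACG[CT]))")


@dataclass
class MotifHit:
    region_id: str
    pwm_id: str
    offset: int  # reference-relative, 0-based window start
    strand: str
    normalized_score: float
    conserved: bool = False
    length: int = 5


@dataclass
class AlignedRegion:
    """A genomic interval with per-species gapped alignment rows."""

    region_id: str
    chrom: str
    start: int
    end: int
    species_rows: dict[str, str]  # insertion-ordered; first row = reference
    gene_id: str = ""

    def __post_init__(self):
        lengths = {len(s) for s in self.species_rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.region_id}: alignment rows differ in length")
        ref = self.reference_row
        cols = [i for i, ch in enumerate(ref) if ch != "-"]
        if not cols:
            raise ValueError(f"{self.region_id}: reference row is all gaps")
        self.colmap = np.asarray(cols)

    @property
    def reference_species(self) -> str:
        return next(iter(self.species_rows))

    @property
    def reference_row(self) -> str:
        return next(iter(self.species_rows.values()))

    @cached_property
    def reference_seq(self) -> str:
        return self.reference_row.replace("-", "").upper()

    def __len__(self) -> int:
        return len(self.reference_seq)

    @cached_property
    def base_matrix(self) -> np.ndarray:
        """(n_species, ref_length) base codes at reference positions.

        Gaps and unknown bases are code 4 and never match anything.
        """
        rows = []
        for seq in self.species_rows.values():
            rows.append(encode(seq.upper().replace("-", "N"))[self.colmap])
        return np.vstack(rows)

    @cached_property
    def species_index(self) -> dict[str, int]:
        return {sp: i for i, sp in enumerate(self.species_rows)}


def read_aligned_fasta(text: str) -> AlignedRegion:
    """Read one region alignment from FASTA.

    The first record is the reference species; its header is
    ``>species region_id chrom:start-end``, remaining records ``>species``.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) < 2:
        raise ValueError("aligned FASTA needs at least two species rows")
    ref = records[0]
    fields = ref.description.split()
    if len(fields) < 3:
        raise ValueError(
            f"reference header must be 'species region_id chrom:start-end', got {ref.description!r}"
        )
    species, region_id, locus = fields[0], fields[1], fields[2]
    m = re.fullmatch(r"(.+):(\d+)-(\d+)", locus)
    if not m:
        raise ValueError(f"bad locus {locus!r} in header of {region_id!r}")
    rows = {species: str(ref.seq)}
    for rec in records[1:]:
        rows[rec.id] = str(rec.seq)
    region = AlignedRegion(
        region_id=region_id, chrom=m.group(1), start=int(m.group(2)),
        end=int(m.group(3)), species_rows=rows,
    )
    if len(region) != region.end - region.start:
        raise ValueError(
            f"{region_id}: degapped reference length {len(region)} != interval span"
        )
    return region


def write_aligned_fasta(region: AlignedRegion) -> str:
    out = []
    for i, (sp, seq) in enumerate(region.species_rows.items()):
        if i == 0:
            out.append(f">{sp} {region.region_id} {region.chrom}:{region.start}-{region.end}")
        else:
            out.append(f">{sp}")
        out.append(seq)
    return "\n".join(out) + "\n"


def find_rcgtg(region: AlignedRegion, both_strands: bool = True) -> list[MotifHit]:
    """All RCGTG (R = A/G) consensus occurrences on the reference sequence.

    Minus-strand occurrences are CACGY matches reported at their
    plus-strand offsets.
    """
    seq = region.reference_seq
    hits = [
        MotifHit(region.region_id, RCGTG_ID, m.start(), "+", 1.0)
        for m in _RCGTG_FWD.finditer(seq)
    ]
    if both_strands:
        hits += [
            MotifHit(region.region_id, RCGTG_ID, m.start(), "-", 1.0)
            for m in _RCGTG_REV.finditer(seq)
        ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def is_conserved(hit: MotifHit, region: AlignedRegion, ic_mask=None,
                 min_species: int = 4, required_species=None) -> bool:
    """Identity-based conservation test at the masked motif positions.

    True iff at least ``min_species`` species (the reference counts) carry
    the reference base at every masked position, and every species in
    ``required_species`` is among them.  For minus-strand hits the same
    alignment columns are tested (base identity is strand-symmetric), with
    the mask reversed to follow motif orientation.
    """
    L = hit.length
    if ic_mask is None:
        mask = np.ones(L, dtype=bool)
    else:
        mask = np.asarray(ic_mask, dtype=bool)
        if mask.size != L:
            raise ValueError("ic_mask length must equal motif length")
        if hit.strand == "-":
            mask = mask[::-1]
    if required_species is None:
        required_species = {region.reference_species, "mouse"}
    offsets = hit.offset + np.nonzero(mask)[0]
    if offsets.size == 0:
        offsets = np.array([hit.offset])  # no informative position: check anchor base
    bm = region.base_matrix
    ref_bases = bm[0, offsets]
    matches = ((bm[:, offsets] == ref_bases) & (bm[:, offsets] != 4)).all(axis=1)
    if np.any(ref_bases == 4):
        return False
    idx = region.species_index
    for sp in required_species:
        if sp not in idx or not matches[idx[sp]]:
            return False
    return int(matches.sum()) >= min_species


def scan_region(region: AlignedRegion, pwm: PWM, threshold: float,
                both_strands: bool = False, min_species: int = 4,
                required_species=None) -> list[MotifHit]:
    """All PWM windows scoring >= threshold, annotated with conservation.

    Hits failing the conservation filter are retained with
    ``conserved=False`` so callers can inspect the unfiltered scan.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    codes = encode(region.reference_seq)
    hits: list[MotifHit] = []
    strands = ["+"] + (["-"] if both_strands else [])
    for strand in strands:
        scores = pwm.scan_codes(codes, reverse=(strand == "-"))
        for off in np.nonzero(scores >= threshold)[0]:
            hit = MotifHit(region.region_id, pwm.id, int(off), strand,
                           float(scores[off]), length=pwm.length)
            hit.conserved = is_conserved(hit, region, pwm.ic_mask,
                                         min_species, required_species)
            hits.append(hit)
    return hits


def presence_matrix(regions, pwms, thresholds: dict, stringency: str = "minFP",
                    both_strands: bool = False, min_species: int = 4,
                    required_species=None) -> pd.DataFrame:
    """Binary region x PWM matrix of conserved-hit presence.

    A cell is 1 iff the region holds at least one hit above the chosen
    stringency's threshold that passes the conservation filter.
    """
    for pwm in pwms:
        if pwm.id not in thresholds:
            raise KeyError(f"no calibrated thresholds for PWM {pwm.id!r}")
    data = np.zeros((len(regions), len(pwms)), dtype=int)
    for j, pwm in enumerate(pwms):
        t = thresholds[pwm.id][stringency]
        for i, region in enumerate(regions):
            hits = scan_region(region, pwm, t, both_strands, min_species,
                               required_species)
            data[i, j] = int(any(h.conserved for h in hits))
    return pd.DataFrame(data, index=[r.region_id for r in regions],
                        columns=[p.id for p in pwms])


def hits_to_bed(hits, regions_by_id: dict) -> str:
    """BED6 lines for hits (score column = 1000 * normalized score)."""
    lines = []
    for h in hits:
        r = regions_by_id[h.region_id]
        start = r.start + h.offset
        lines.append(
            f"{r.chrom}\t{start}\t{start + h.length}\t{h.pwm_id}"
            f"\t{int(round(1000 * h.normalized_score))}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits) -> str:
    lines = ["region_id\tpwm_id\toffset\tstrand\tnormalized_score\tconserved"]
    for h in hits:
        lines.append(
            f"{h.region_id}\t{h.pwm_id}\t{h.offset}\t{h.strand}"
            f"\t{h.normalized_score:.6g}\t{int(h.conserved)}"
        )
    return "\n".join(lines) + "\n"
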