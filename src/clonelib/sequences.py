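"""Marker-gene sequence handling: FASTA IO, degenerate-primer matching,
primer-bounded region extraction and G+C content.

Clone libraries are Sanger-sequenced PCR amplicons (~900 bp partial 16S
rRNA, mcrA or dsrB genes). Growth-temperature inference needs the internal
16S region flanked by the archaeal primers 109F/915R, trimmed to a common
length (800 bp by convention), and its G+C percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "SequenceRecord",
    "Primer",
    "RegionInterval",
    "ExtractedRegion",
    "FastaParseError",
    "PrimerNotFoundError",
    "AmbiguousPrimerSiteError",
    "DEFAULT_PRIMERS",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_match",
    "find_primer_sites",
    "extract_region",
    "gc_percent",
]

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they allow.
#: 'U' is treated as 'T' throughout.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "U": "A", "G": "C", "C": "G",
    "M": "K", "K": "M", "R": "Y", "Y": "R", "W": "W", "S": "S",
    "V": "B", "B": "V", "H": "D", "D": "H", "N": "N", "-": "-",
}

_VALID_RESIDUES = frozenset(IUPAC_DNA) | {"-"}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class PrimerNotFoundError(ValueError):
    """No primer site within the allowed mismatch budget."""


class AmbiguousPrimerSiteError(ValueError):
    """More than one candidate primer site; positions listed in the message."""


@dataclass(frozen=True)
class SequenceRecord:
    """One clone sequence. Residues are upper-case IUPAC DNA, '-' for gaps."""

    id: str
    residues: str
    description: str = ""
    is_aligned: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} empty or contains whitespace")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC symbols: {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class Primer:
    """A PCR primer given as an IUPAC-degenerate pattern.

    Reverse primers are written 5'->3' as synthesized; they are matched
    against the target via the reverse complement of their pattern.
    """

    name: str
    pattern: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"primer {self.name!r}: empty pattern")
        if "-" in self.pattern:
            raise ValueError(f"primer {self.name!r}: gaps not allowed in pattern")
        bad = set(self.pattern) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"primer {self.name!r}: illegal symbols {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: orientation must be forward|reverse")


#: Standard published primer sequences shipped as overridable defaults.
#: The exact primer variants used by any particular study may differ;
#: override via config (`primers.forward` / `primers.reverse`).
DEFAULT_PRIMERS: dict[str, Primer] = {
    "109F": Primer("109F", "ACKGCTCAGTAACACGT", "forward"),
    "915R": Primer("915R", "GTGCTCCCCCGCCAATTCCT", "reverse"),
    "27F": Primer("27F", "AGAGTTTGATCMTGGCTCAG", "forward"),
    "907R": Primer("907R", "CCGTCAATTCMTTTRAGTTT", "reverse"),
}


class RegionInterval(NamedTuple):
    """0-based half-open interval on the ungapped sequence."""

    start: int
    end: int
    strand: str = "+"


class ExtractedRegion(NamedTuple):
    sequence: str
    interval: RegionInterval
    is_short: bool


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Record order and descriptions are preserved; residues are upper-cased.
    Illegal residue symbols raise :class:`FastaParseError` naming the line.
    """
    # validation pass with line numbers (Bio.SeqIO does not report them)
    with open(path) as fh:
        lines = fh.readlines()
    in_record = False
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith(">"):
            in_record = True
            if len(text) == 1:
                raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
            continue
        if not in_record:
            raise FastaParseError(
                f"{path}: sequence data before any '>' header at line {lineno}"
            )
        bad = set(text.upper()) - _VALID_RESIDUES
        if bad:
            raise FastaParseError(
                f"{path}: illegal residue symbol(s) {sorted(bad)} at line {lineno}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                description=desc,
                is_aligned="-" in residues,
            )
        )
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement symbol {exc.args[0]!r}") from exc


def iupac_match(pattern: str, window: str, max_mismatch: int = 0) -> bool:
    """True iff `window` matches the degenerate `pattern` with at most
    `max_mismatch` positions where the window base is outside the pattern
    symbol's allowed set. 'N' in the pattern matches anything."""
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    mismatches = 0
    for p, w in zip(pattern.upper(), window.upper()):
        allowed = IUPAC_DNA.get(p)
        if allowed is None:
            raise ValueError(f"illegal pattern symbol {p!r}")
        if w not in allowed:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def find_primer_sites(seq: str, primer: Primer, max_mismatch: int = 0) -> list[RegionInterval]:
    """All primer-site intervals on the forward strand of `seq`.

    Forward primers are matched as-is; reverse primers via the reverse
    complement of their pattern (the hit interval is reported on the
    forward strand with strand '-')."""
    if primer.orientation == "reverse":
        pattern = reverse_complement(primer.pattern)
        strand = "-"
    else:
        pattern = primer.pattern
        strand = "+"
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        if iupac_match(pattern, seq[i : i + k], max_mismatch):
            hits.append(RegionInterval(i, i + k, strand))
    return hits


def _unique_site(seq: str, primer: Primer, max_mismatch: int) -> RegionInterval:
    hits = find_primer_sites(seq, primer, max_mismatch)
    if not hits:
        raise PrimerNotFoundError(
            f"primer not found: {primer.name} within {max_mismatch} mismatch(es)"
        )
    if len(hits) > 1:
        raise AmbiguousPrimerSiteError(
            f"ambiguous primer site for {primer.name}: candidates at "
            f"{[(h.start, h.end) for h in hits]}"
        )
    return hits[0]


def extract_region(
    seq: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 1,
    target_len: int = 800,
    length_tolerance: int = 20,
) -> ExtractedRegion:
    """Extract the subsequence strictly between the forward and reverse
    primer sites, center-cropped to `target_len` if longer.

    A region shorter than `target_len` by at most `length_tolerance` is
    returned as-is with `is_short=True` (and a warning); shorter still is
    an error. Multiple candidate sites for either primer are an error
    rather than a silent first-hit pick.
    """
    ungapped = seq.ungapped().upper()
    fwd_site = _unique_site(ungapped, fwd, max_mismatch)
    rev_site = _unique_site(ungapped, rev, max_mismatch)
    start, end = fwd_site.end, rev_site.start
    if end <= start:
        raise PrimerNotFoundError(
            f"{seq.id}: reverse primer site does not lie downstream of forward site"
        )
    region = ungapped[start:end]
    is_short = False
    if len(region) > target_len:
        # symmetric center-crop; an odd surplus leaves one extra base on the left trim
        surplus = len(region) - target_len
        left = surplus // 2
        start += left
        end = start + target_len
        region = ungapped[start:end]
    elif len(region) < target_len:
        if target_len - len(region) > length_tolerance:
            raise PrimerNotFoundError(
                f"{seq.id}: extracted region length {len(region)} is more than "
                f"{length_tolerance} bp short of target {target_len}"
            )
        is_short = True
        warnings.warn(
            f"{seq.id}: region length {len(region)} < target {target_len}; kept as-is",
            stacklevel=2,
        )
    return ExtractedRegion(region, RegionInterval(start, end, "+"), is_short)


def gc_percent(region: str, include_ambiguous: bool = False) -> float:
    """G+C percentage of an ungapped DNA region, to 2 decimal places.

    Numerator counts G, C and S (G-or-C, GC-certain). By default the
    denominator counts only GC-informative bases (A, C, G, T, U, S, W);
    other ambiguity codes are excluded so they do not bias the estimate.
    With `include_ambiguous=True` every base counts in the denominator.
    """
    if not region:
        raise ValueError("empty region")
    if "-" in region:
        raise ValueError("region must be ungapped")
    up = region.upper()
    bad = set(up) - set(IUPAC_DNA)
    if bad:
        raise ValueError(f"illegal residue symbol(s) {sorted(bad)}")
    gc = sum(up.count(c) for c in "GCS")
    if include_ambiguous:
        denom = len(up)
    else:
        denom = sum(up.count(c) for c in "ACGTUSW")
    if denom == 0:
        raise ValueError("region contains no GC-informative bases")
    return round(100.0 * gc / denom, 2)
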