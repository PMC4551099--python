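"""FASTA IO, degenerate-primer matching, region extraction and G+C."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonelib.sequences import (
    DEFAULT_PRIMERS,
    AmbiguousPrimerSiteError,
    ExtractedRegion,
    FastaParseError,
    IUPAC_DNA,
    Primer,
    PrimerNotFoundError,
    SequenceRecord,
    extract_region,
    gc_percent,
    iupac_match,
    read_fasta,
    reverse_complement,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


# --- FASTA ----------------------------------------------------------------


def test_read_fasta_preserves_order_and_descriptions(tmp_path):
    p = tmp_path / "two.fasta"
    p.write_text(">c1 first clone\nacgt\nACGT\n>c2 second\nTTTT\n")
    recs = read_fasta(p)
    assert [r.id for r in recs] == ["c1", "c2"]
    assert recs[0].residues == "ACGTACGT"  # wrapped lines joined, upper-cased
    assert recs[0].description == "first clone"


def test_read_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p) == []


def test_read_fasta_illegal_residue_names_line(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">c1\nACGT\nAXGT\n")
    with pytest.raises(FastaParseError, match="line 3"):
        read_fasta(p)


def test_fasta_roundtrip(tmp_path):
    recs = [
        SequenceRecord("a", "ACGT" * 40, "desc one"),
        SequenceRecord("b", "TTGGCCAA"),
    ]
    p = tmp_path / "rt.fasta"
    write_fasta(recs, p)
    back = read_fasta(p)
    assert [(r.id, r.residues, r.description) for r in back] == [
        (r.id, r.residues, r.description) for r in recs
    ]


def test_sequence_record_validation():
    with pytest.raises(ValueError):
        SequenceRecord("has space", "ACGT")
    with pytest.raises(ValueError):
        SequenceRecord("ok", "")
    with pytest.raises(ValueError):
        SequenceRecord("ok", "ACXT")


# --- IUPAC matching -------------------------------------------------------


def _expansion_match(pattern, window, max_mismatch):
    """Independent oracle: expand the pattern into explicit base sets."""
    mism = sum(1 for p, w in zip(pattern, window) if w not in IUPAC_DNA[p])
    return mism <= max_mismatch


@pytest.mark.parametrize(
    "pattern,window,k,expected",
    [
        ("ACKG", "ACGG", 0, True),  # K = G or T
        ("ACKG", "ACTG", 0, True),
        ("ACKG", "ACAG", 0, False),
        ("ACGT", "ACGA", 0, False),
        ("ACGT", "ACGA", 1, True),
        ("NNNN", "TGCA", 0, True),  # N matches anything
    ],
)
def test_iupac_match_examples(pattern, window, k, expected):
    assert iupac_match(pattern, window, k) is expected


def test_iupac_match_length_mismatch():
    with pytest.raises(ValueError):
        iupac_match("ACG", "ACGT")


def test_iupac_match_exhaustive_vs_expansion_oracle():
    """All 256 4-mers against 'RYSW', every mismatch budget."""
    for window in map("".join, itertools.product("ACGT", repeat=4)):
        for k in range(3):
            assert iupac_match("RYSW", window, k) == _expansion_match("RYSW", window, k)


@given(
    pattern=st.text(alphabet=sorted(IUPAC_DNA), min_size=1, max_size=6),
    window=st.text(alphabet="ACGT", min_size=6, max_size=6),
    k=st.integers(0, 3),
)
def test_iupac_match_agrees_with_oracle(pattern, window, k):
    w = window[: len(pattern)]
    assert iupac_match(pattern, w, k) == _expansion_match(pattern, w, k)


# --- G+C content ----------------------------------------------------------


@pytest.mark.parametrize(
    "region,expected",
    [("GGCC", 100.0), ("ATAT", 0.0), ("G" * 440 + "A" * 360, 55.0)],
)
def test_gc_percent_examples(region, expected):
    assert gc_percent(region) == expected


def test_gc_percent_ambiguity_handling():
    # S is GC-certain; N excluded from both sides by default
    assert gc_percent("GSNN") == 100.0
    assert gc_percent("GSNN", include_ambiguous=True) == 50.0
    with pytest.raises(ValueError):
        gc_percent("NNNN")
    with pytest.raises(ValueError):
        gc_percent("")
    with pytest.raises(ValueError):
        gc_percent("AC-GT")


@given(dna)
def test_gc_percent_reverse_complement_invariant(seq):
    assert gc_percent(seq) == gc_percent(reverse_complement(seq))


# --- region extraction ----------------------------------------------------

FWD = Primer("fwd", "ACGGATTAGATACCCTGG", "forward")
REV = Primer("rev", "GAATTGGCACGGGTTTCC", "reverse")


def _flanked(region, pad5="", pad3=""):
    return SequenceRecord(
        "q", pad5 + FWD.pattern + region + reverse_complement(REV.pattern) + pad3
    )


def test_extract_region_recovers_planted_800mer(rng):
    region = "".join(rng.choice(list("ACGT"), size=800))
    out = extract_region(_flanked(region, "AAA", "TT"), FWD, REV, 0, 800)
    assert out.sequence == region
    assert not out.is_short


def test_extract_region_center_crops_longer_region(rng):
    region = "".join(rng.choice(list("ACGT"), size=812))
    out = extract_region(_flanked(region), FWD, REV, 0, 800)
    # oracle by index arithmetic on the construction: surplus 12, trim 6 each side
    assert out.sequence == region[6:806]


def test_extract_region_short_region_flagged(rng):
    region = "".join(rng.choice(list("ACGT"), size=790))
    with pytest.warns(UserWarning, match="790"):
        out = extract_region(_flanked(region), FWD, REV, 0, 800)
    assert out.is_short and out.sequence == region


def test_extract_region_too_short_errors(rng):
    region = "".join(rng.choice(list("ACGT"), size=700))
    with pytest.raises(PrimerNotFoundError, match="short"):
        extract_region(_flanked(region), FWD, REV, 0, 800)


def test_extract_region_missing_reverse_primer(rng):
    region = "".join(rng.choice(list("ACGT"), size=100))
    rec = SequenceRecord("q", FWD.pattern + region)
    with pytest.raises(PrimerNotFoundError, match="primer not found"):
        extract_region(rec, FWD, REV, 0, 100)


def test_extract_region_ambiguous_site_errors(rng):
    region = "".join(rng.choice(list("ACGT"), size=50))
    rec = SequenceRecord(
        "q",
        FWD.pattern + region + FWD.pattern + region
        + reverse_complement(REV.pattern),
    )
    with pytest.raises(AmbiguousPrimerSiteError, match="fwd"):
        extract_region(rec, FWD, REV, 0, 100)


def test_extract_region_strips_gaps(rng):
    region = "".join(rng.choice(list("ACGT"), size=100))
    gappy = FWD.pattern + "--" + region[:50] + "---" + region[50:] \
        + reverse_complement(REV.pattern)
    out = extract_region(SequenceRecord("q", gappy), FWD, REV, 0, 100)
    assert out.sequence == region


@given(
    st.integers(0, 2**31 - 1),
    st.integers(0, 2),
)
def test_extract_region_planted_recovery_with_primer_mismatches(seed, n_mut):
    """Planted region recovered byte-for-byte for any mismatch count
    within the budget, including mutated primer sites."""
    import numpy as np

    r = np.random.default_rng(seed)
    region = "".join(r.choice(list("ACGT"), size=200))
    fwd_site = list(FWD.pattern)
    for pos in r.choice(len(fwd_site), size=n_mut, replace=False):
        fwd_site[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd_site[pos]]
    rec = SequenceRecord(
        "q", "".join(fwd_site) + region + reverse_complement(REV.pattern)
    )
    out = extract_region(rec, FWD, REV, max_mismatch=n_mut, target_len=200)
    assert out.sequence == region


def test_default_primers_are_valid():
    for p in DEFAULT_PRIMERS.values():
        assert set(p.pattern) <= set(IUPAC_DNA)
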