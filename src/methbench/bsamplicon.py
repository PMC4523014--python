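"""Bisulfite amplicon sequencing analysis.

Reads from a bisulfite-converted amplicon are aligned to a
cytosine-masked reference, quality-filtered (> 90% identity outside
bisulfite-modifiable sites and > 90% reference coverage), projected onto
reference coordinates, and summarised two ways:

* **site-based estimate (SBE)** — at each methylation-informative site
  (the C of a CpG in the untreated reference) score the non-conversion
  fraction Ccount/(Ccount+Tcount) across reads, then average over sites;
* **read-based estimate (RBE)** — classify each read by its fraction of
  converted informative sites (methylated <= 20% converted, unmethylated
  >= 80%, otherwise indeterminate) and report
  100 * methylated / (methylated + unmethylated).

The two estimators respond differently to PCR chimeras: a crossover
between a methylated and an unmethylated molecule leaves per-site counts
(SBE) untouched but produces mixed reads that inflate the indeterminate
class, so SBE/RBE divergence is a chimerism diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import PairwiseAlignment, Scoring, align_local, encode, revcomp

__all__ = [
    "MaskedReference",
    "ReadAlignment",
    "SiteTable",
    "ReadClassification",
    "mask_reference",
    "align_read",
    "filter_alignment",
    "project_to_reference",
    "build_site_table",
    "site_based_estimate",
    "classify_reads",
    "read_based_estimate",
    "demultiplex",
    "analyze_sample",
]

GAP = -1  # projected call for a reference position deleted in the read

#: Read-classification thresholds on the converted-site fraction.
METHYLATED_MAX_CONVERTED = 0.20
UNMETHYLATED_MIN_CONVERTED = 0.80

#: Minimum fraction of informative sites a read must cover (with a C or
#: T call) to be classified at all.
MIN_SITE_COVERAGE = 0.5

IDENTITY_MIN = 0.90
COVERAGE_MIN = 0.90

_CODE_TO_BASE = np.array(list("ACGTN"))


@dataclass(frozen=True)
class MaskedReference:
    """Reference sequence with its bisulfite-modifiable positions.

    ``c_positions`` are all reference cytosines (any C can read as T
    after conversion); ``informative_sites`` are the Cs of CpG
    dinucleotides, the only positions where methylation protects the C.
    """

    sequence: str
    c_positions: tuple[int, ...]
    informative_sites: tuple[int, ...]
    encoded: np.ndarray = field(repr=False, compare=False, default=None)
    mask: np.ndarray = field(repr=False, compare=False, default=None)

    def __len__(self) -> int:
        return len(self.sequence)


def mask_reference(sequence: str) -> MaskedReference:
    """Record the modifiable (C) and informative (CpG) positions of an
    amplicon reference.  Masked positions score C or T as a match during
    alignment, removing the alignment bias between converted and
    unconverted molecules."""
    seq = sequence.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError("reference must be non-empty and contain only A/C/G/T")
    c_pos = tuple(i for i, b in enumerate(seq) if b == "C")
    info = tuple(
        i for i in c_pos if i + 1 < len(seq) and seq[i + 1] == "G"
    )
    enc = encode(seq)
    mask = np.zeros(len(seq), dtype=np.bool_)
    mask[list(c_pos)] = True
    return MaskedReference(seq, c_pos, info, enc, mask)


@dataclass(frozen=True)
class ReadAlignment:
    """A filtered-alignment candidate for one read."""

    read_id: str
    alignment: PairwiseAlignment
    identity: float
    coverage: float
    reverse: bool

    @property
    def ref_interval(self) -> tuple[int, int]:
        return self.alignment.ref_start, self.alignment.ref_end


def _identity_coverage(
    aln: PairwiseAlignment, read_codes: np.ndarray, ref: MaskedReference
) -> tuple[float, float]:
    if aln.pairs.shape[0] == 0:
        return 0.0, 0.0
    ref_idx = aln.pairs[:, 0]
    read_idx = aln.pairs[:, 1]
    # identity over aligned, non-modifiable reference positions; a
    # deletion at such a position counts against identity
    considered = 0
    matched = 0
    for r, q in zip(ref_idx, read_idx):
        if r < 0 or ref.mask[r]:
            continue
        considered += 1
        if q >= 0 and read_codes[q] == ref.encoded[r]:
            matched += 1
    identity = matched / considered if considered else 0.0
    coverage = (aln.ref_end - aln.ref_start) / len(ref)
    return identity, coverage


def align_read(
    read: str,
    ref: MaskedReference,
    read_id: str = "",
    scoring: Scoring = Scoring(),
) -> ReadAlignment:
    """Align one read in both orientations and keep the better one.

    The forward orientation is tried first and accepted outright when it
    already clears the identity/coverage filter (a read cannot pass in
    both orientations); otherwise the reverse complement is aligned and
    the higher-scoring candidate returned.  Reverse reads are mapped via
    their reverse complement so the C/T masking rule applies unchanged.
    """
    if not read:
        raise ValueError("empty read")
    fwd_codes = encode(read)
    fwd = align_local(fwd_codes, ref.encoded, ref.mask, scoring)
    fid, fcov = _identity_coverage(fwd, fwd_codes, ref)
    if fid > IDENTITY_MIN and fcov > COVERAGE_MIN:
        return ReadAlignment(read_id, fwd, fid, fcov, reverse=False)
    rev_codes = encode(revcomp(read))
    rev = align_local(rev_codes, ref.encoded, ref.mask, scoring)
    rid, rcov = _identity_coverage(rev, rev_codes, ref)
    if rev.score > fwd.score:
        return ReadAlignment(read_id, rev, rid, rcov, reverse=True)
    return ReadAlignment(read_id, fwd, fid, fcov, reverse=False)


def filter_alignment(aln: ReadAlignment) -> bool:
    """Strict quality filter: identity > 90% (outside modifiable sites)
    AND reference coverage > 90%.  Exactly 90% fails."""
    return aln.identity > IDENTITY_MIN and aln.coverage > COVERAGE_MIN


def project_to_reference(
    alns: Sequence[ReadAlignment],
    reads: Mapping[str, str],
    ref: MaskedReference,
) -> np.ndarray:
    """Reference-anchored projection of passed alignments.

    Returns an int matrix (reads x reference length): base code 0-3 at
    aligned positions, ``GAP`` (-1) where the reference position is
    deleted in the read, -2 where the read does not cover the position.
    Read insertions relative to the reference are dropped, i.e. gap
    columns in the reference are removed.
    """
    calls = np.full((len(alns), len(ref)), -2, dtype=np.int8)
    for row, aln in enumerate(alns):
        seq = reads[aln.read_id]
        codes = encode(revcomp(seq)) if aln.reverse else encode(seq)
        for r, q in aln.alignment.pairs:
            if r < 0:
                continue  # insertion in the read: not a reference column
            calls[row, r] = codes[q] if q >= 0 else GAP
    return calls


@dataclass(frozen=True)
class SiteTable:
    """Per-informative-site C/T counts and non-conversion fractions."""

    sites: tuple[int, ...]
    c_counts: np.ndarray
    t_counts: np.ndarray
    depth: np.ndarray

    @property
    def non_conversion(self) -> np.ndarray:
        """Ccount/(Ccount+Tcount) per site; NaN where no C/T call."""
        tot = self.c_counts + self.t_counts
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, self.c_counts / np.maximum(tot, 1), np.nan)


def build_site_table(calls: np.ndarray, ref: MaskedReference) -> SiteTable:
    """Count C and T calls at each informative site across the
    projected read matrix.  Depth counts reads with any base call."""
    sites = ref.informative_sites
    sub = calls[:, list(sites)] if len(sites) else np.empty((calls.shape[0], 0))
    c_counts = (sub == 1).sum(axis=0)
    t_counts = (sub == 3).sum(axis=0)
    depth = (sub >= 0).sum(axis=0)
    return SiteTable(tuple(sites), np.asarray(c_counts), np.asarray(t_counts),
                     np.asarray(depth))


def site_based_estimate(table: SiteTable) -> float:
    """SBE: 100 x mean non-conversion over covered informative sites.

    Sites with no C/T call are excluded from the mean rather than
    imputed; an entirely uncovered amplicon raises.
    """
    nc = table.non_conversion
    covered = nc[~np.isnan(nc)]
    if covered.size == 0:
        raise ValueError("no informative site has coverage; SBE undefined")
    return 100.0 * float(covered.mean())


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    n_sites_covered: int
    converted_fraction: float | None
    label: str  # methylated | unmethylated | indeterminate | uncovered


def classify_reads(
    calls: np.ndarray, ref: MaskedReference, read_ids: Sequence[str]
) -> list[ReadClassification]:
    """Classify each projected read by its converted-site fraction.

    Conversion at a site means a T call where the untreated template had
    the CpG cytosine.  Reads covering fewer than half of the informative
    sites (with a C or T call) are labelled ``uncovered`` and take no
    part in the read-based estimate.
    """
    sites = list(ref.informative_sites)
    n_sites = len(sites)
    out: list[ReadClassification] = []
    for row, rid in enumerate(read_ids):
        site_calls = calls[row, sites]
        is_c = site_calls == 1
        is_t = site_calls == 3
        n_ct = int(is_c.sum() + is_t.sum())
        if n_sites == 0 or n_ct < MIN_SITE_COVERAGE * n_sites:
            out.append(ReadClassification(rid, n_ct, None, "uncovered"))
            continue
        conv = float(is_t.sum()) / n_ct
        if conv <= METHYLATED_MAX_CONVERTED:
            label = "methylated"
        elif conv >= UNMETHYLATED_MIN_CONVERTED:
            label = "unmethylated"
        else:
            label = "indeterminate"
        out.append(ReadClassification(rid, n_ct, conv, label))
    return out


def read_based_estimate(
    classes: Iterable[ReadClassification],
) -> tuple[float, dict[str, float]]:
    """RBE: 100 x methylated / (methylated + unmethylated), ignoring
    indeterminate reads.  Also returns the class fractions among
    classified (covered) reads; the indeterminate fraction should stay
    well under 1% for clean single-molecule amplicons."""
    counts = {"methylated": 0, "unmethylated": 0, "indeterminate": 0}
    for c in classes:
        if c.label in counts:
            counts[c.label] += 1
    m, u = counts["methylated"], counts["unmethylated"]
    if m + u == 0:
        raise ValueError("no classifiable reads; RBE undefined")
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    return 100.0 * m / (m + u), fractions


def demultiplex(
    reads: Sequence[tuple[str, str]], mid_table: Mapping[str, str]
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str]]]:
    """Assign reads to samples by exact multiplex-identifier prefix.

    ``mid_table`` maps sample name -> MID tag sequence.  Returns
    per-sample read lists (every sample present, possibly empty) plus
    the unassigned bin.  Duplicate tags are a table error.
    """
    tags = list(mid_table.values())
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate MID tags in table")
    by_sample: dict[str, list[tuple[str, str]]] = {s: [] for s in mid_table}
    unassigned: list[tuple[str, str]] = []
    items = sorted(mid_table.items(), key=lambda kv: -len(kv[1]))
    for rid, seq in reads:
        for sample, tag in items:
            if seq.startswith(tag):
                by_sample[sample].append((rid, seq))
                break
        else:
            unassigned.append((rid, seq))
    return by_sample, unassigned


def analyze_sample(
    reads: Sequence[tuple[str, str]],
    ref: MaskedReference,
    scoring: Scoring = Scoring(),
) -> dict:
    """Full per-sample analysis: align, filter, project, estimate.

    Returns a summary dict with the site table, per-read classes, SBE,
    RBE, class fractions and filter counts.
    """
    read_map = dict(reads)
    passed: list[ReadAlignment] = []
    n_failed = 0
    for rid, seq in reads:
        aln = align_read(seq, ref, read_id=rid, scoring=scoring)
        if filter_alignment(aln):
            passed.append(aln)
        else:
            n_failed += 1
    if not passed:
        raise ValueError("no read passed the alignment quality filter")
    calls = project_to_reference(passed, read_map, ref)
    table = build_site_table(calls, ref)
    classes = classify_reads(calls, ref, [a.read_id for a in passed])
    sbe = site_based_estimate(table)
    rbe, fractions = read_based_estimate(classes)
    return {
        "n_reads": len(reads),
        "n_passed": len(passed),
        "n_failed_filter": n_failed,
        "site_table": table,
        "classes": classes,
        "sbe": sbe,
        "rbe": rbe,
        "class_fractions": fractions,
    }
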