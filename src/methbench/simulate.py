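"""Synthetic data with the statistical structure each estimator assumes.

The generator emulates a benchmarking experiment on a seven-member panel
of genomic DNA standards mixed from fully methylated and fully
unmethylated genomes (100/90/75/50/25/10/0% methylated, ~1515 haploid
genome equivalents per reaction):

* restriction digestion as binomial survival with configurable enzyme
  efficiency and non-specific template loss, next to a mock digest;
* qPCR as Cq values on a perfect-doubling standard curve with ~0.2-cycle
  technical noise (zero template never amplifies);
* digital PCR as uniform assignment of molecules to 770-chamber panels,
  with a duplex mode that tracks the two non-complementary single
  strands of bisulfite-converted DNA separately;
* bisulfite amplicon reads over a synthetic 205-nt reference with 19
  CpG sites, with tunable conversion failure, per-base sequencing
  error, homopolymer indels, per-barcode (MID) amplification bias,
  methylation-dependent PCR bias and PCR chimera formation.

Every generator is a pure function of its inputs and seed.  Molecules
are all-or-none methylated, matching standards mixed from fully
methylated and fully unmethylated genomic DNA; mosaic per-site
methylation is deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bsamplicon import MaskedReference, analyze_sample, mask_reference
from .core import (
    DEFAULT_PANEL_FRACTIONS,
    EnzymeClass,
    EnzymeKind,
    MDRE,
    MSRE,
    Method,
    MethylationEstimate,
    PanelStandard,
)
from .dpcr import (
    ChamberMatrix,
    PanelCount,
    estimated_targets,
    methylight_dpcr_percent,
    pool_panels,
    re_dpcr_percent,
    combine_duplex,
)
from .qpcr import (
    StandardCurve,
    UNDETECTED,
    interpolate_copies,
    mean_cq,
    methylight_qpcr_percent,
    re_qpcr_percent,
)

__all__ = [
    "SimulationConfig",
    "PanelDataset",
    "DEFAULT_CURVE",
    "synthetic_reference",
    "default_mid_table",
    "simulate_digestion",
    "simulate_qpcr",
    "simulate_dpcr",
    "simulate_duplex_dpcr",
    "simulate_bisulfite_reads",
    "simulate_panel_experiment",
    "quantify_re_qpcr",
    "quantify_re_dpcr",
    "quantify_methylight_qpcr",
    "quantify_methylight_dpcr",
    "quantify_ngs",
]

#: Perfect-doubling calibration: slope -1/log10(2) Cq per decade, one
#: copy crossing at cycle 40.
DEFAULT_CURVE = StandardCurve(slope=-3.3219280948873623, intercept=40.0, r_squared=1.0)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic panel experiment.

    Defaults follow the benchmark's operating regime: ~1515 genome
    copies (5 ng) per reaction, 0.2-cycle Cq noise, 770-chamber dPCR
    panels loaded so that lambda stays below 0.2, 500 reads per sample
    at 99.5% bisulfite conversion and 1% sequencing error.  The MDRE
    digestion is slightly incomplete by default (98% efficient) because
    fully methylated template is never driven entirely to completion.
    """

    panel_fractions: tuple[float, ...] = DEFAULT_PANEL_FRACTIONS
    copies_per_reaction: int = 1515
    cq_sigma: float = 0.2
    n_qpcr_wells: int = 3
    re_replicates: int = 3
    msre_efficiency: float = 1.0
    mdre_efficiency: float = 0.98
    nonspecific_loss: float = 0.0
    partitions_per_panel: int = 770
    re_dpcr_panels: int = 4
    ml_dpcr_panels: int = 1
    #: fraction of the reaction volume that ends up inside chambers
    dpcr_loaded_fraction: float = 0.13
    #: MethyLight reactions load a quarter of the RE template amount
    #: (1.25 of 5 uL), which keeps chamber occupancy under lambda 0.2
    ml_template_fraction: float = 0.25
    reads_per_sample: int = 500
    conversion_rate: float = 0.995
    seq_error: float = 0.01
    homopolymer_indel_rate: float = 0.002
    mid_bias: dict = field(default_factory=dict)
    methylation_pcr_bias: float = 1.0
    chimera_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "msre_efficiency", "mdre_efficiency", "nonspecific_loss",
            "dpcr_loaded_fraction", "conversion_rate", "seq_error",
            "homopolymer_indel_rate", "chimera_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.methylation_pcr_bias <= 0:
            raise ValueError("methylation_pcr_bias must be positive")

    def unbiased(self) -> "SimulationConfig":
        """The idealised counterpart: complete digestion and conversion,
        error-free sequencing, no loss, no PCR or barcode bias, no
        chimeras.  The measurement architecture's own noise — Cq sigma,
        Poisson partitioning, finite read sampling — remains, so
        estimates still scatter but carry no systematic shift."""
        return dataclasses.replace(
            self,
            msre_efficiency=1.0,
            mdre_efficiency=1.0,
            nonspecific_loss=0.0,
            conversion_rate=1.0,
            seq_error=0.0,
            homopolymer_indel_rate=0.0,
            mid_bias={},
            methylation_pcr_bias=1.0,
            chimera_rate=0.0,
        )


# ---------------------------------------------------------------------------
# reference and barcodes


def synthetic_reference(
    length: int = 205, n_cpg: int = 19, seed: int = 1
) -> MaskedReference:
    """Construct an amplicon reference with exactly ``n_cpg`` CpG sites.

    The default dimensions (205 nt, 19 CpGs) match a typical CpG-island
    promoter amplicon.  CpG dinucleotides are placed at spaced positions
    and the remaining sequence is filled so that no additional CpG
    arises; non-CpG cytosines are retained so that conversion of
    ordinary Cs is represented.
    """
    if length < 3 * n_cpg:
        raise ValueError("reference too short for the requested CpG count")
    rng = np.random.default_rng(seed)
    # CpG start positions, spaced at least 3 apart so sites never abut
    positions = np.sort(rng.choice((length - 2) // 3, size=n_cpg, replace=False)) * 3
    seq = [""] * length
    cpg_starts = set(int(p) for p in positions)
    occupied = set()
    for p in cpg_starts:
        seq[p] = "C"
        seq[p + 1] = "G"
        occupied.update((p, p + 1))
    for i in range(length):
        if i in occupied:
            continue
        while True:
            b = str(rng.choice(_BASES))
            prev = seq[i - 1] if i > 0 else ""
            nxt = seq[i + 1] if i + 1 < length else ""
            if b == "G" and prev == "C" and i - 1 not in cpg_starts:
                continue  # would create an extra CpG
            if b == "C" and nxt == "G":
                continue
            seq[i] = b
            break
    return mask_reference("".join(seq))


def default_mid_table(n: int = 10, tag_length: int = 10, seed: int = 7) -> dict[str, str]:
    """Synthetic multiplex-identifier tags: ``n`` distinct ``tag_length``-mers
    with pairwise Hamming distance >= 3, keyed MID1..MIDn."""
    rng = np.random.default_rng(seed)
    tags: list[str] = []
    while len(tags) < n:
        cand = "".join(rng.choice(_BASES, size=tag_length))
        if all(sum(a != b for a, b in zip(cand, t)) >= 3 for t in tags):
            tags.append(cand)
    return {f"MID{i + 1}": t for i, t in enumerate(tags)}


# ---------------------------------------------------------------------------
# enzymatic digestion


def simulate_digestion(
    copies: int,
    fraction_methylated: float,
    enzyme: EnzymeClass,
    efficiency: float,
    nonspecific_loss: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Binomial survival of a digestion reaction plus its mock control.

    MSRE cleaves unmethylated recognition sites, so methylated molecules
    survive and unmethylated ones escape with probability
    ``1 - efficiency``; MDRE is the mirror image.  The mock digest sees
    only non-specific loss, which also applies to the true digests.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    meth = int(rng.binomial(copies, fraction_methylated))
    unmeth = copies - meth
    if enzyme.kind is EnzymeKind.MSRE:
        survivors = meth + int(rng.binomial(unmeth, 1.0 - efficiency))
    else:
        survivors = unmeth + int(rng.binomial(meth, 1.0 - efficiency))
    keep = 1.0 - nonspecific_loss
    digest = int(rng.binomial(survivors, keep))
    mock = int(rng.binomial(copies, keep))
    return {"digest": digest, "mock": mock, "methylated": meth, "unmethylated": unmeth}


# ---------------------------------------------------------------------------
# measurement layers


def simulate_qpcr(
    copies: float,
    curve: StandardCurve = DEFAULT_CURVE,
    sigma: float = 0.2,
    n_wells: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Replicate Cq wells for a template amount on a standard curve.

    Cq = intercept + slope * log10(copies) + N(0, sigma); zero template
    yields UNDETECTED in every well.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if copies <= 0:
        return tuple([UNDETECTED] * n_wells)
    base = curve.intercept + curve.slope * np.log10(copies)
    return tuple(float(base + rng.normal(0.0, sigma)) for _ in range(n_wells))


def simulate_dpcr(
    molecules: int,
    n_partitions: int = 770,
    seed: int | np.random.Generator = 0,
) -> PanelCount:
    """Uniform assignment of molecules to chambers; a chamber is
    positive iff it received at least one molecule."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if molecules == 0:
        return PanelCount(0, n_partitions)
    chambers = rng.integers(0, n_partitions, size=molecules)
    return PanelCount(int(np.unique(chambers).size), n_partitions)


def simulate_duplex_dpcr(
    molecules_a: int,
    molecules_b: int,
    n_partitions: int = 770,
    paired: int = 0,
    seed: int | np.random.Generator = 0,
) -> ChamberMatrix:
    """Two-channel chamber calls for a duplex assay.

    ``molecules_a``/``molecules_b`` are independently partitioned single
    strands (the post-bisulfite case: the two strands of each source
    duplex are no longer complementary and separate).  ``paired``
    molecules model *double-stranded* template: each occupies one
    chamber and lights both channels.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.zeros(n_partitions, dtype=bool)
    b = np.zeros(n_partitions, dtype=bool)
    if molecules_a:
        a[rng.integers(0, n_partitions, size=molecules_a)] = True
    if molecules_b:
        b[rng.integers(0, n_partitions, size=molecules_b)] = True
    if paired:
        where = rng.integers(0, n_partitions, size=paired)
        a[where] = True
        b[where] = True
    return ChamberMatrix(a, b)


# ---------------------------------------------------------------------------
# bisulfite reads


def _convert_molecule(
    ref: MaskedReference, methylated: bool, conversion_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    codes = ref.encoded.copy()
    c_pos = np.array(ref.c_positions, dtype=np.int64)
    info = set(ref.informative_sites)
    is_info = np.array([p in info for p in c_pos])
    u = rng.random(c_pos.size)
    if methylated:
        # CpG cytosines are protected; conversion failure still converts
        # them at rate 1 - conversion_rate.  Non-CpG Cs are unmethylated
        # and convert normally.
        to_t = np.where(is_info, u < (1.0 - conversion_rate), u < conversion_rate)
    else:
        to_t = u < conversion_rate
    codes[c_pos[to_t]] = 3  # T
    return codes


def _apply_sequencing_noise(
    codes: np.ndarray, seq_error: float, indel_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = codes.copy()
    if seq_error > 0:
        err = rng.random(out.size) < seq_error
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            out[err] = (out[err] + shift) % 4
    if indel_rate > 0:
        pieces: list[int] = []
        prev = -1
        run = 0
        for b in out:
            run = run + 1 if b == prev else 1
            prev = int(b)
            if run >= 2 and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion within a homopolymer
                pieces.append(int(b))  # duplication
            pieces.append(int(b))
        out = np.array(pieces, dtype=out.dtype)
    return out


def simulate_bisulfite_reads(
    fraction_methylated: float,
    ref: MaskedReference,
    config: SimulationConfig = SimulationConfig(),
    n_reads: int | None = None,
    mid_name: str = "",
    mid_tag: str = "",
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Amplicon reads from one panel sample plus their ground truth.

    Each source molecule is fully methylated (probability weighted by
    the methylation PCR bias and any per-MID bias on methylated
    templates) or fully unmethylated; bisulfite conversion, sequencing
    substitutions, homopolymer indels and PCR chimeras are then applied,
    and the MID tag is prepended.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = config.reads_per_sample if n_reads is None else n_reads
    beta = config.methylation_pcr_bias * config.mid_bias.get(mid_name, 1.0)
    f = fraction_methylated
    p_meth = (f * beta) / (f * beta + (1.0 - f)) if f > 0 else 0.0
    reads: list[tuple[str, str]] = []
    states: list[bool] = []
    n_chimeric = 0
    for i in range(n):
        methylated = bool(rng.random() < p_meth)
        codes = _convert_molecule(ref, methylated, config.conversion_rate, rng)
        if config.chimera_rate > 0 and rng.random() < config.chimera_rate:
            other = bool(rng.random() < p_meth)
            codes2 = _convert_molecule(ref, other, config.conversion_rate, rng)
            bp = int(rng.integers(1, len(ref)))
            codes = np.concatenate([codes[:bp], codes2[bp:]])
            n_chimeric += 1
        codes = _apply_sequencing_noise(
            codes, config.seq_error, config.homopolymer_indel_rate, rng
        )
        seq = mid_tag + "".join(_BASES[codes])
        rid = f"{mid_name or 'sample'}_read{i}"
        reads.append((rid, seq))
        states.append(methylated)
    truth = {
        "fraction_methylated": f,
        "sampling_p_methylated": p_meth,
        "n_methylated": int(sum(states)),
        "n_reads": n,
        "n_chimeric": n_chimeric,
        "read_states": states,
    }
    return reads, truth


# ---------------------------------------------------------------------------
# full panel experiment


@dataclass
class PanelDataset:
    """Everything one synthetic benchmarking experiment produces."""

    config: SimulationConfig
    panel: list[PanelStandard]
    curve: StandardCurve
    reference: MaskedReference
    mid_table: dict[str, str]
    # re_qpcr[(label, enzyme_kind, replicate)] = {"digest": wells, "mock": wells}
    re_qpcr: dict
    # re_dpcr[(label, enzyme_kind, replicate)] = {"digest": PanelCount, "mock": PanelCount}
    re_dpcr: dict
    # ml_qpcr[(label, replicate)] = {"p14": wells, "col2a1": wells}
    ml_qpcr: dict
    # ml_dpcr[(label, replicate)] = {"p14": PanelCount, "col2a1": PanelCount,
    #                                "duplex": ChamberMatrix}
    ml_dpcr: dict
    # ngs[label] = {"reads": [...], "mid": name, "truth": {...}}
    ngs: dict
    truth: dict


def _label(fraction: float) -> str:
    return f"{round(100 * fraction):g}%"


def simulate_panel_experiment(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
    include_ngs: bool = True,
) -> PanelDataset:
    """Generate one complete synthetic experiment over the panel.

    Deterministic for a fixed (config, seed); each assay family draws
    from its own child stream so adding one assay never perturbs
    another.
    """
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    rng_re, rng_ml, rng_ngs = (np.random.default_rng(s) for s in ss.spawn(3))
    panel = [PanelStandard(_label(f), f) for f in config.panel_fractions]
    copies = config.copies_per_reaction
    curve = DEFAULT_CURVE

    re_qpcr: dict = {}
    re_dpcr: dict = {}
    for std in panel:
        for enzyme in (MSRE, MDRE):
            eff = (
                config.msre_efficiency
                if enzyme.kind is EnzymeKind.MSRE
                else config.mdre_efficiency
            )
            for rep in range(config.re_replicates):
                dig = simulate_digestion(
                    copies, std.expected_fraction, enzyme, eff,
                    config.nonspecific_loss, rng_re,
                )
                key = (std.label, enzyme.kind.value, rep)
                re_qpcr[key] = {
                    "digest": simulate_qpcr(
                        dig["digest"], curve, config.cq_sigma,
                        config.n_qpcr_wells, rng_re,
                    ),
                    "mock": simulate_qpcr(
                        dig["mock"], curve, config.cq_sigma,
                        config.n_qpcr_wells, rng_re,
                    ),
                }
                loaded_dig = int(rng_re.binomial(dig["digest"], config.dpcr_loaded_fraction))
                loaded_mock = int(rng_re.binomial(dig["mock"], config.dpcr_loaded_fraction))
                n_pool = config.partitions_per_panel * config.re_dpcr_panels
                re_dpcr[key] = {
                    "digest": simulate_dpcr(loaded_dig, n_pool, rng_re),
                    "mock": simulate_dpcr(loaded_mock, n_pool, rng_re),
                }

    ml_qpcr: dict = {}
    ml_dpcr: dict = {}
    for std in panel:
        for rep in range(config.re_replicates):
            meth = int(rng_ml.binomial(copies, std.expected_fraction))
            ml_qpcr[(std.label, rep)] = {
                "p14": simulate_qpcr(meth, curve, config.cq_sigma, 2, rng_ml),
                "col2a1": simulate_qpcr(copies, curve, config.cq_sigma, 2, rng_ml),
            }
            load_p = config.dpcr_loaded_fraction * config.ml_template_fraction
            loaded_meth = int(rng_ml.binomial(meth, load_p))
            loaded_all = int(rng_ml.binomial(copies, load_p))
            n_ml = config.partitions_per_panel * config.ml_dpcr_panels
            ml_dpcr[(std.label, rep)] = {
                "p14": simulate_dpcr(loaded_meth, n_ml, rng_ml),
                "col2a1": simulate_dpcr(loaded_all, n_ml, rng_ml),
                # each methylated genome contributes one molecule per strand
                "duplex": simulate_duplex_dpcr(
                    loaded_meth, int(rng_ml.binomial(meth, load_p)),
                    n_ml, 0, rng_ml,
                ),
            }

    reference = synthetic_reference()
    mid_table = default_mid_table(max(10, len(panel)))
    ngs: dict = {}
    if include_ngs:
        mids = list(mid_table)
        for idx, std in enumerate(panel):
            mid = mids[idx % len(mids)]
            reads, truth = simulate_bisulfite_reads(
                std.expected_fraction, reference, config,
                mid_name=mid, mid_tag=mid_table[mid], seed=rng_ngs,
            )
            ngs[std.label] = {"reads": reads, "mid": mid, "truth": truth}

    truth = {std.label: std.expected_percent for std in panel}
    return PanelDataset(
        config=config, panel=panel, curve=curve, reference=reference,
        mid_table=mid_table, re_qpcr=re_qpcr, re_dpcr=re_dpcr,
        ml_qpcr=ml_qpcr, ml_dpcr=ml_dpcr, ngs=ngs, truth=truth,
    )


# ---------------------------------------------------------------------------
# estimator drivers (simulated data in, MethylationEstimate out)


def _control_label(ds: PanelDataset, enzyme: EnzymeClass) -> str:
    frac = 1.0 if enzyme.kind is EnzymeKind.MSRE else 0.0
    return _label(frac)


def quantify_re_qpcr(ds: PanelDataset, enzyme: EnzymeClass) -> list[MethylationEstimate]:
    """Run the ddCq calculation per sample and replicate."""
    ctrl = _control_label(ds, enzyme)
    method = Method.MSRE_QPCR if enzyme.kind is EnzymeKind.MSRE else Method.MDRE_QPCR
    out = []
    for std in ds.panel:
        for rep in range(ds.config.re_replicates):
            sk = (std.label, enzyme.kind.value, rep)
            ck = (ctrl, enzyme.kind.value, rep)
            res = re_qpcr_percent(
                ds.re_qpcr[sk]["digest"], ds.re_qpcr[sk]["mock"],
                ds.re_qpcr[ck]["digest"], ds.re_qpcr[ck]["mock"], enzyme,
            )
            out.append(MethylationEstimate(
                res.percent, method, rep, std.expected_percent, std.label
            ))
    return out


def quantify_re_dpcr(ds: PanelDataset, enzyme: EnzymeClass) -> list[MethylationEstimate]:
    """Run the Poisson %RQ calculation per sample and replicate."""
    ctrl = _control_label(ds, enzyme)
    method = Method.MSRE_DPCR if enzyme.kind is EnzymeKind.MSRE else Method.MDRE_DPCR
    out = []
    for std in ds.panel:
        for rep in range(ds.config.re_replicates):
            sk = (std.label, enzyme.kind.value, rep)
            ck = (ctrl, enzyme.kind.value, rep)
            c_dig = estimated_targets(ds.re_dpcr[ck]["digest"])
            c_mock = estimated_targets(ds.re_dpcr[ck]["mock"])
            control_rq = c_dig.targets / c_mock.targets
            s_dig = estimated_targets(ds.re_dpcr[sk]["digest"])
            s_mock = estimated_targets(ds.re_dpcr[sk]["mock"])
            if enzyme.kind is EnzymeKind.MSRE:
                if control_rq <= 0:
                    raise ValueError("MSRE control fully digested; cannot normalise")
                pct = re_dpcr_percent(s_dig, s_mock, control_rq, enzyme)
            else:
                # the 0% control survives MDRE intact
                pct = re_dpcr_percent(s_dig, s_mock, control_rq, enzyme)
            out.append(MethylationEstimate(
                pct, method, rep, std.expected_percent, std.label
            ))
    return out


def quantify_methylight_qpcr(ds: PanelDataset) -> list[MethylationEstimate]:
    """Standard-curve MethyLight quantification with COL2A1 normalisation."""
    ctrl = _label(1.0)
    out = []
    for rep in range(ds.config.re_replicates):
        ratios = {}
        for std in ds.panel:
            wells = ds.ml_qpcr[(std.label, rep)]
            p14_cq = mean_cq(wells["p14"]).mean
            col_cq = mean_cq(wells["col2a1"]).mean
            p14_copies, _ = interpolate_copies(ds.curve, p14_cq)
            col_copies, det = interpolate_copies(ds.curve, col_cq)
            if not det:
                raise ValueError(f"COL2A1 undetected for {std.label}")
            ratios[std.label] = p14_copies / col_copies
        ref_ratio = ratios[ctrl]
        for std in ds.panel:
            pct = 100.0 * ratios[std.label] / ref_ratio
            out.append(MethylationEstimate(
                pct, Method.ML_QPCR, rep, std.expected_percent, std.label
            ))
    return out


def quantify_methylight_dpcr(
    ds: PanelDataset, duplex: bool = False
) -> list[MethylationEstimate]:
    """Singleplex (one strand) or duplex (both strands combined)
    MethyLight dPCR, normalised to COL2A1 and the 100% sample."""
    ctrl = _label(1.0)
    method = Method.ML_DPCR_DUPLEX if duplex else Method.ML_DPCR_SINGLE
    out = []
    for rep in range(ds.config.re_replicates):
        ratios = {}
        for std in ds.panel:
            d = ds.ml_dpcr[(std.label, rep)]
            col = estimated_targets(d["col2a1"])
            if duplex:
                ka, kb = d["duplex"].counts()
                p14 = combine_duplex(estimated_targets(ka), estimated_targets(kb))
                # two strands per genome on the p14 side, one counted for COL2A1
                ratios[std.label] = p14.targets / (2.0 * col.targets)
            else:
                p14 = estimated_targets(d["p14"])
                ratios[std.label] = p14.targets / col.targets
        ref_ratio = ratios[ctrl]
        for std in ds.panel:
            pct = methylight_dpcr_percent(ratios[std.label], 1.0, ref_ratio)
            out.append(MethylationEstimate(
                pct, method, rep, std.expected_percent, std.label
            ))
    return out


def quantify_ngs(ds: PanelDataset) -> tuple[list[MethylationEstimate], dict]:
    """Align and summarise the simulated reads of every sample; returns
    site-based and read-based estimates plus per-sample summaries."""
    out = []
    summaries = {}
    for std in ds.panel:
        entry = ds.ngs[std.label]
        summary = analyze_sample(entry["reads"], ds.reference)
        summaries[std.label] = summary
        out.append(MethylationEstimate(
            summary["sbe"], Method.NGS_SBE, 0, std.expected_percent, std.label
        ))
        out.append(MethylationEstimate(
            summary["rbe"], Method.NGS_RBE, 0, std.expected_percent, std.label
        ))
    return out, summaries
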