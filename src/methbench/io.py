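"""File formats: FASTA reads/references and the CSV shapes emitted by
the simulator and consumed by the quantification commands.

All CSVs are comma-separated with a header row, UTF-8, '.' decimal;
percent methylation is always on the 0-100 scale.  An empty ``cq`` cell
means the well did not amplify (UNDETECTED).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dpcr import ChamberMatrix, PanelCount
from .qpcr import UNDETECTED

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_cq_csv",
    "write_cq_csv",
    "read_dpcr_counts",
    "write_dpcr_counts",
    "read_chamber_matrix",
    "write_chamber_matrix",
    "read_manifest",
    "write_manifest",
    "write_dataset",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Order-preserving FASTA reader returning (id, sequence) pairs.

    Raises ``ValueError`` with the offending line number when the first
    record header is missing or a header line is empty.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected a '>' header, got {stripped[:30]!r}"
                )
            if stripped == ">":
                raise ValueError(f"{path}:{lineno}: empty FASTA header")
            break
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def write_cq_csv(path: str | Path, rows: Sequence[dict]) -> None:
    """Write well-level Cq rows; UNDETECTED becomes an empty cell."""
    df = pd.DataFrame(rows)
    if "cq" in df.columns:
        df["cq"] = df["cq"].map(lambda v: "" if v is UNDETECTED else v)
    df.to_csv(path, index=False)


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    """Read a well-level Cq table; empty cells become UNDETECTED."""
    df = pd.read_csv(path)
    df["cq"] = df["cq"].map(lambda v: UNDETECTED if pd.isna(v) else float(v))
    return df


def write_dpcr_counts(path: str | Path, rows: Sequence[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dpcr_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("k", "n"):
        df[col] = df[col].astype(int)
    return df


def write_chamber_matrix(
    path: str | Path, rows: Sequence[dict]
) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chamber_matrix(path: str | Path) -> dict[tuple, ChamberMatrix]:
    """Read per-chamber duplex calls grouped by (sample, replicate)."""
    df = pd.read_csv(path)
    out = {}
    for key, g in df.groupby(["sample", "replicate"]):
        g = g.sort_values("chamber")
        out[key] = ChamberMatrix(
            g["call_a"].astype(bool).to_numpy(),
            g["call_b"].astype(bool).to_numpy(),
        )
    return out


def write_manifest(path: str | Path, panel) -> None:
    pd.DataFrame(
        [
            {
                "label": s.label,
                "expected_percent": s.expected_percent,
                "mass_ng": s.nominal_mass,
            }
            for s in panel
        ]
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"label", "expected_percent"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def write_removal_log(path: str | Path, removals: Sequence[dict]) -> None:
    """Write viability-filter removals as JSON lines, one per estimate."""
    with open(path, "w") as fh:
        for record in removals:
            fh.write(json.dumps(record) + "\n")


def _safe(label: str) -> str:
    return label.replace("%", "pct")


def write_dataset(ds, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated :class:`~methbench.simulate.PanelDataset` as the
    file set the quantification commands read.  Returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["manifest"] = out / "manifest.csv"
    write_manifest(paths["manifest"], ds.panel)

    rows = []
    for (sample, enzyme, rep), d in ds.re_qpcr.items():
        for treatment in ("digest", "mock"):
            for w, cq in enumerate(d[treatment]):
                rows.append(
                    {"sample": sample, "enzyme": enzyme, "replicate": rep,
                     "treatment": treatment, "well": w, "cq": cq}
                )
    paths["re_qpcr"] = out / "re_qpcr_cq.csv"
    write_cq_csv(paths["re_qpcr"], rows)

    rows = []
    for (sample, enzyme, rep), d in ds.re_dpcr.items():
        for treatment in ("digest", "mock"):
            c: PanelCount = d[treatment]
            rows.append(
                {"sample": sample, "enzyme": enzyme, "replicate": rep,
                 "treatment": treatment, "k": c.k, "n": c.n}
            )
    paths["re_dpcr"] = out / "re_dpcr_counts.csv"
    write_dpcr_counts(paths["re_dpcr"], rows)

    rows = []
    for (sample, rep), d in ds.ml_qpcr.items():
        for assay in ("p14", "col2a1"):
            for w, cq in enumerate(d[assay]):
                rows.append(
                    {"sample": sample, "replicate": rep, "assay": assay,
                     "well": w, "cq": cq}
                )
    paths["ml_qpcr"] = out / "ml_qpcr_cq.csv"
    write_cq_csv(paths["ml_qpcr"], rows)

    rows = []
    duplex_rows = []
    for (sample, rep), d in ds.ml_dpcr.items():
        for assay in ("p14", "col2a1"):
            c = d[assay]
            rows.append(
                {"sample": sample, "replicate": rep, "assay": assay,
                 "k": c.k, "n": c.n}
            )
        cm: ChamberMatrix = d["duplex"]
        for ch in range(cm.n):
            duplex_rows.append(
                {"sample": sample, "replicate": rep, "chamber": ch,
                 "call_a": int(cm.call_a[ch]), "call_b": int(cm.call_b[ch])}
            )
    paths["ml_dpcr"] = out / "ml_dpcr_counts.csv"
    write_dpcr_counts(paths["ml_dpcr"], rows)
    paths["duplex"] = out / "duplex_chambers.csv"
    write_chamber_matrix(paths["duplex"], duplex_rows)

    paths["reference"] = out / "reference.fasta"
    write_fasta(paths["reference"], [("reference", ds.reference.sequence)])

    if ds.ngs:
        mid_rows = []
        pooled = []
        for label, entry in ds.ngs.items():
            fasta = out / f"reads_{_safe(label)}.fasta"
            write_fasta(fasta, entry["reads"])
            paths[f"reads_{label}"] = fasta
            pooled.extend(entry["reads"])
            mid_rows.append(
                {"sample": label, "mid": entry["mid"],
                 "tag": ds.mid_table[entry["mid"]]}
            )
        paths["reads_pooled"] = out / "reads_pooled.fasta"
        write_fasta(paths["reads_pooled"], pooled)
        paths["mid_table"] = out / "mid_table.csv"
        pd.DataFrame(mid_rows).to_csv(paths["mid_table"], index=False)

    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "expected_percent": ds.truth,
                "seed": ds.config.seed,
                "ngs": {
                    label: {k: v for k, v in e["truth"].items() if k != "read_states"}
                    for label, e in ds.ngs.items()
                },
            },
            fh,
            indent=2,
        )
    return paths
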