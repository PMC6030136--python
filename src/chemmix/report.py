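"""Result serialization: p-value formatting, CSV/JSON writers, workbook.

All writers are deterministic: rows come pre-sorted from the analysis
layer and files are written with "\\n" line endings, so writing the same
report twice yields byte-identical output.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import DomainError
from .mixture import JointPValue, MixtureReport

__all__ = ["format_pvalue", "write_report", "shared_terms_frame", "targets_frame"]

TARGET_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "gene_id",
    "gene_name",
    "combined_score",
]


def format_pvalue(p: float | None = None, log10_p: float | None = None) -> str:
    """Format a probability in 3-significant-figure scientific notation.

    Either ``p`` (a probability in [0, 1]) or ``log10_p`` (its base-10
    logarithm) must be given. The log10 path renders magnitudes that
    underflow a float, e.g. log10_p = -67.01 -> "9.75E-68".
    """
    if (p is None) == (log10_p is None):
        raise DomainError("give exactly one of p or log10_p")
    if p is not None:
        if not math.isfinite(p) or p < 0.0 or p > 1.0:
            raise DomainError(f"p must lie in [0, 1], got {p}")
        return f"{p:.2E}"
    if not math.isfinite(log10_p):
        raise DomainError(f"log10_p must be finite, got {log10_p}")
    if log10_p > 0.0:
        raise DomainError(f"log10_p of a probability must be <= 0, got {log10_p}")
    exponent = math.floor(log10_p)
    mantissa = 10.0 ** (log10_p - exponent)
    if round(mantissa, 2) >= 10.0:  # e.g. log10_p = -0.0000001
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.2f}E{exponent:+03d}"


def _format_joint(j: JointPValue) -> str:
    if j.joint_p > 0.0:
        return format_pvalue(j.joint_p)
    if math.isinf(j.log10_joint_p):
        return "0.00E+00"
    return format_pvalue(log10_p=j.log10_joint_p)


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", label)


def targets_frame(report: MixtureReport, chemical_id: str) -> pd.DataFrame:
    """Per-protein target detail rows for one chemical."""
    ts = report.target_sets[chemical_id]
    return pd.DataFrame(ts.protein_details, columns=TARGET_COLUMNS)


def shared_terms_frame(
    report: MixtureReport, namespace: str
) -> pd.DataFrame:
    """Shared-term table: per-chemical adjusted p columns plus joint p.

    ``joint_p`` is the 3-significant-figure formatted value; the
    full-precision product and its log10 are carried in companion columns.
    """
    labels = report.labels
    columns = (
        ["term_id", "description"]
        + [f"p_adj_{_safe_name(label)}" for label in labels]
        + ["joint_p", "joint_p_exact", "log10_joint_p"]
    )
    descriptions: dict[str, str] = {}
    for chem in report.chemicals:
        table = report.per_chemical_enrichment.get((chem, namespace))
        if table is not None:
            for rec in table.records:
                descriptions.setdefault(rec.term_id, rec.description)
    rows = []
    for j in report.shared_terms[namespace]:
        rows.append(
            [j.term_id, descriptions.get(j.term_id, "")]
            + [j.per_chemical_adj_p[label] for label in labels]
            + [_format_joint(j), j.joint_p, j.log10_joint_p]
        )
    return pd.DataFrame(rows, columns=columns)


def write_report(
    report: MixtureReport,
    outdir: str | Path,
    formats: Sequence[str] = ("csv", "json"),
) -> dict[str, str]:
    """Write a mixture report to ``outdir``; returns {name: filename}.

    Emits per-chemical target and enrichment CSVs, a venn_regions.json
    covering targets and per-namespace terms, per-namespace shared-term
    and overall-enrichment CSVs, and (with "xlsx" in ``formats``) a
    workbook whose sheets mirror the CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    manifest: dict[str, str] = {}
    frames: dict[str, pd.DataFrame] = {}

    for chem, label in zip(report.chemicals, report.labels):
        frames[f"targets_{_safe_name(label)}"] = targets_frame(report, chem)
    for (chem, ns), table in sorted(report.per_chemical_enrichment.items()):
        label = report.label_for(chem)
        frames[f"enrichment_{_safe_name(label)}_{_safe_name(ns)}"] = table.to_frame()
    for ns in sorted(report.shared_terms):
        frames[f"shared_terms_{_safe_name(ns)}"] = shared_terms_frame(report, ns)
    for ns, table in sorted(report.overall_enrichment.items()):
        frames[f"overall_enrichment_{_safe_name(ns)}"] = table.to_frame()

    if "csv" in formats:
        for name in sorted(frames):
            path = outdir / f"{name}.csv"
            frames[name].to_csv(path, index=False, lineterminator="\n")
            manifest[name] = path.name

    if "json" in formats:
        venn = {
            "targets": report.target_venn.to_json_dict(),
            "terms": {
                ns: report.term_venn[ns].to_json_dict()
                for ns in sorted(report.term_venn)
            },
        }
        path = outdir / "venn_regions.json"
        with open(path, "w", encoding="utf-8", newline="") as handle:
            json.dump(venn, handle, indent=2, sort_keys=True)
            handle.write("\n")
        manifest["venn_regions"] = path.name

    if "xlsx" in formats:
        path = outdir / "report.xlsx"
        used: set[str] = set()
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name in sorted(frames):
                frames[name].to_excel(
                    writer, sheet_name=_sheet_name(name, used), index=False
                )
        manifest["workbook"] = path.name

    return manifest


def _sheet_name(name: str, used: set[str]) -> str:
    # Excel sheet names are capped at 31 characters; keep them unique
    sheet = name[:31]
    counter = 1
    while sheet in used:
        suffix = f"~{counter}"
        sheet = name[: 31 - len(suffix)] + suffix
        counter += 1
    used.add(sheet)
    return sheet
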