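"""Readers and writers for the pipeline's flat-file interfaces.

Chip readouts travel as a CSV with one row per chip and the exact header
``sample_id,chip_id,panel,n_wells,n_fam_only,n_vic_only,n_double,n_negative,
dilution_factor``; downstream outputs are a per-channel quantification CSV, a
per-sample report TSV, a dilution-series TSV and an evaluation JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .caller import SampleReport
from .core import PANELS, ChipReadout, QuantResult
from .evaluate import CohortEvaluation, DilutionSeriesResult
from .simulate import DilutionChip

CHIP_CSV_COLUMNS = [
    "sample_id", "chip_id", "panel", "n_wells",
    "n_fam_only", "n_vic_only", "n_double", "n_negative", "dilution_factor",
]

__all__ = [
    "CHIP_CSV_COLUMNS",
    "read_chip_csv",
    "write_chip_csv",
    "write_quant_csv",
    "write_report_tsv",
    "write_dilution_tsv",
    "write_evaluation_json",
]


def read_chip_csv(path: "str | Path") -> List[ChipReadout]:
    """Load and validate chip readouts; rejects malformed rows by row number."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CHIP_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    readouts: List[ChipReadout] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, after the header line
        try:
            panel = PANELS[str(row["panel"])]
        except KeyError:
            raise ValueError(f"{path}:{rowno}: unknown panel {row['panel']!r}") from None
        try:
            counts = {
                c: int(row[c])
                for c in ("n_wells", "n_fam_only", "n_vic_only", "n_double", "n_negative")
            }
            dil = float(row["dilution_factor"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{rowno}: non-numeric count or dilution factor") from None
        try:
            readouts.append(
                ChipReadout(
                    sample_id=str(row["sample_id"]),
                    chip_id=str(row["chip_id"]),
                    panel=panel,
                    dilution_factor=dil,
                    **counts,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{rowno}: {exc}") from None
    return readouts


def write_chip_csv(readouts: Sequence[ChipReadout], path: "str | Path") -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "chip_id": r.chip_id,
            "panel": r.panel.panel_id,
            "n_wells": r.n_wells,
            "n_fam_only": r.n_fam_only,
            "n_vic_only": r.n_vic_only,
            "n_double": r.n_double,
            "n_negative": r.n_negative,
            "dilution_factor": r.dilution_factor,
        }
        for r in readouts
    ]
    pd.DataFrame(rows, columns=CHIP_CSV_COLUMNS).to_csv(path, index=False)


def write_quant_csv(
    quants: Sequence[tuple[ChipReadout, Mapping[str, QuantResult]]], path: "str | Path"
) -> None:
    """Per-channel quantification table: one row per chip per dye channel."""
    rows = []
    for readout, per_channel in quants:
        for channel, q in per_channel.items():
            rows.append(
                {
                    "sample_id": readout.sample_id,
                    "chip_id": readout.chip_id,
                    "panel": readout.panel.panel_id,
                    "channel": channel,
                    "p_hat": q.p_hat,
                    "lambda": q.occupancy,
                    "conc_copies_per_ul": q.concentration,
                    "ci_low": q.ci_low,
                    "ci_high": q.ci_high,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chip_id", "panel", "channel", "p_hat",
            "lambda", "conc_copies_per_ul", "ci_low", "ci_high",
        ],
    ).to_csv(path, index=False)


def _fmt_ratio(report: SampleReport, chrom: str) -> str:
    call = report.autosome_calls.get(chrom)
    return f"{call.ratio.ratio:.4f}" if call else "NA"


def write_report_tsv(reports: Sequence[SampleReport], path: "str | Path") -> None:
    rows = []
    for rep in reports:
        qc_failed = [c.chip_id for c in rep.chip_qc if not c.passed]
        rows.append(
            {
                "sample_id": rep.sample_id,
                "chr13_ratio": _fmt_ratio(rep, "13"),
                "chr18_ratio": _fmt_ratio(rep, "18"),
                "chr21_ratio": _fmt_ratio(rep, "21"),
                "sex_ratio": f"{rep.sex_call.x_autosome_ratio:.4f}" if rep.sex_call else "NA",
                "sry_detected": str(rep.sex_call.sry_detected).lower() if rep.sex_call else "NA",
                "call_13": rep.autosome_calls["13"].call if "13" in rep.autosome_calls else "no_call",
                "call_18": rep.autosome_calls["18"].call if "18" in rep.autosome_calls else "no_call",
                "call_21": rep.autosome_calls["21"].call if "21" in rep.autosome_calls else "no_call",
                "call_sex": rep.sex_call.call if rep.sex_call else "no_call",
                "flags": ";".join(sorted(rep.flags)) or ".",
                "qc": "pass" if not qc_failed else "fail:" + ";".join(qc_failed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dilution_tsv(chips: Sequence[DilutionChip], ratios: Sequence[float], path: "str | Path") -> None:
    rows = [
        {
            "fraction": c.fraction,
            "replicate": c.replicate,
            "ratio": r,
            "theoretical_ratio": 1.0 + c.fraction / 2.0,
        }
        for c, r in zip(chips, ratios)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_evaluation_json(
    evaluation: CohortEvaluation,
    path: "str | Path",
    dilution: Mapping[str, DilutionSeriesResult] | None = None,
) -> None:
    payload: Dict[str, dict] = {"threshold": evaluation.threshold, "per_trisomy": {}}
    for chrom, ev in evaluation.per_trisomy.items():
        payload["per_trisomy"][f"T{chrom}"] = {
            "n_aneuploid": ev.n_aneuploid,
            "n_euploid": ev.n_euploid,
            "U": ev.mannwhitney_u,
            "p": ev.p_two_sided,
            "auroc": ev.auroc,
            "auroc_ci": list(ev.auroc_ci),
            "sensitivity": ev.sensitivity,
            "specificity": ev.specificity,
            "confusion": {"tp": ev.tp, "fp": ev.fp, "tn": ev.tn, "fn": ev.fn},
        }
    if dilution:
        payload["dilution"] = {
            f"T{chrom}": {
                "slope": d.slope,
                "intercept": d.intercept,
                "pearson_r": d.pearson_r,
                "r_squared": d.r_squared,
                "detection_limit_fraction": d.detection_limit_fraction,
            }
            for chrom, d in dilution.items()
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
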