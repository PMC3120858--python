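"""Quantification of the two-substrate competitive pull-down binding assay.

An immobilized fluorescent-protein fusion is incubated with two
differentially labelled DNA substrates in direct competition; after
washing, bound DNA and protein amounts are read out as background-
subtracted fluorescence intensities and converted to concentrations with
per-channel calibration factors.  The analysis proceeds in three steps:

1. binding ratio per substrate: bound-DNA concentration divided by
   protein concentration,
2. label-bias correction against a control experiment that used two
   substrates of identical sequence but swapped fluorescent labels —
   implemented as division by the control's ratios (a ratiometric
   label-efficiency model; the minimal correction consistent with
   removing label/detection bias, and flagged as a model assumption in
   all outputs),
3. normalization by total bound DNA, so the two relative ratios sum to 1.

Replicates are summarized as mean with sample standard deviation
(n - 1 denominator), matching the usual three-independent-experiments
error bars.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, StructureError

#: Output-metadata note attached to all correction results.
CORRECTION_MODEL_NOTE = (
    "label-bias correction model: measured ratio divided by control ratio "
    "(ratiometric assumption)"
)

MEASUREMENT_COLUMNS = (
    "replicate_id",
    "substrate_a_fluor",
    "substrate_b_fluor",
    "protein_fluor",
    "calib_a",
    "calib_b",
    "calib_protein",
)


@dataclass(frozen=True)
class CompetitionMeasurement:
    """One replicate of the two-color competition assay.

    Fluorescence intensities are background-subtracted arbitrary units;
    ``calib_*`` convert intensity to concentration (a.u. per nM).
    """

    substrate_a_fluor: float
    substrate_b_fluor: float
    protein_fluor: float
    calib_a: float
    calib_b: float
    calib_protein: float
    replicate_id: str = "r1"

    def __post_init__(self):
        for name in ("calib_a", "calib_b", "calib_protein"):
            if getattr(self, name) <= 0:
                raise StructureError(f"{name} must be positive")
        for name in ("substrate_a_fluor", "substrate_b_fluor", "protein_fluor"):
            if getattr(self, name) < 0:
                raise StructureError(
                    f"{name} must be >= 0 after background subtraction"
                )


def binding_ratios(m: CompetitionMeasurement) -> tuple:
    """Bound-DNA-per-protein ratio for each substrate (unitless).

    ratio_x = (fluor_x / calib_x) / (protein_fluor / calib_protein).
    """
    if m.protein_fluor == 0:
        raise StructureError(
            f"replicate {m.replicate_id}: zero protein signal"
        )
    protein_conc = m.protein_fluor / m.calib_protein
    ratio_a = (m.substrate_a_fluor / m.calib_a) / protein_conc
    ratio_b = (m.substrate_b_fluor / m.calib_b) / protein_conc
    return ratio_a, ratio_b


def correct_and_normalize(ratios: tuple, control_ratios: tuple) -> tuple:
    """Label-bias-corrected relative DNA/protein ratios summing to 1.

    Each ratio is divided by the matching control ratio (same-sequence,
    label-swapped control), then the pair is normalized by its sum.
    """
    ra, rb = ratios
    ca, cb = control_ratios
    if ca <= 0 or cb <= 0:
        raise StructureError("control ratios must be positive")
    corr_a = ra / ca
    corr_b = rb / cb
    total = corr_a + corr_b
    if total == 0:
        raise StructureError(
            "both corrected ratios are zero: relative binding undefined"
        )
    return corr_a / total, corr_b / total


def replicate_summary(values) -> tuple:
    """Mean and sample standard deviation (ddof=1) over replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StructureError("replicate summary needs >= 2 replicates")
    return float(arr.mean()), float(arr.std(ddof=1))


# -- CSV pipeline ----------------------------------------------------------

def _read_measurements(source) -> list:
    text = source
    if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text
                                  and Path(text).is_file()):
        text = Path(text).read_text()
    elif hasattr(text, "read"):
        text = text.read()
    df = pd.read_csv(io.StringIO(text))
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing column(s) {missing}")
    return [
        CompetitionMeasurement(
            substrate_a_fluor=row.substrate_a_fluor,
            substrate_b_fluor=row.substrate_b_fluor,
            protein_fluor=row.protein_fluor,
            calib_a=row.calib_a,
            calib_b=row.calib_b,
            calib_protein=row.calib_protein,
            replicate_id=str(row.replicate_id),
        )
        for row in df.itertuples(index=False)
    ]


def analyze_competition_assay(measurements, controls) -> pd.DataFrame:
    """Full assay pipeline over replicate tables (CSV paths/text or lists).

    Controls are matched to measurements by ``replicate_id`` when both
    define it, else by position.  Returns one row per replicate with the
    relative ratios, plus a ``mean``/``sd`` summary row per substrate
    appended as columns attributes; the correction-model note is stored
    in ``DataFrame.attrs``.
    """
    if not isinstance(measurements, (list, tuple)):
        measurements = _read_measurements(measurements)
    if not isinstance(controls, (list, tuple)):
        controls = _read_measurements(controls)
    if len(controls) == 1 and len(measurements) > 1:
        controls = list(controls) * len(measurements)
    if len(controls) != len(measurements):
        raise SchemaError(
            f"{len(measurements)} measurements but {len(controls)} controls"
        )
    by_id = {c.replicate_id: c for c in controls}
    rows = []
    for k, m in enumerate(measurements):
        control = by_id.get(m.replicate_id, controls[k])
        rel_a, rel_b = correct_and_normalize(
            binding_ratios(m), binding_ratios(control)
        )
        rows.append(
            {"replicate_id": m.replicate_id,
             "relative_ratio_a": rel_a,
             "relative_ratio_b": rel_b}
        )
    df = pd.DataFrame(rows)
    df.attrs["correction_model"] = CORRECTION_MODEL_NOTE
    if len(df) >= 2:
        mean_a, sd_a = replicate_summary(df["relative_ratio_a"])
        mean_b, sd_b = replicate_summary(df["relative_ratio_b"])
        df.attrs["summary"] = {
            "a": {"mean": mean_a, "sd": sd_a},
            "b": {"mean": mean_b, "sd": sd_b},
        }
    return df


def write_assay_report(df: pd.DataFrame, dest=None) -> str | None:
    """CSV report of per-replicate relative ratios plus summary comments."""
    lines = [f"# {df.attrs.get('correction_model', '')}"]
    summary = df.attrs.get("summary")
    if summary:
        lines.append(
            "# summary: a = %.6f +/- %.6f, b = %.6f +/- %.6f"
            % (summary["a"]["mean"], summary["a"]["sd"],
               summary["b"]["mean"], summary["b"]["sd"])
        )
    text = "\n".join(lines) + "\n" + df.to_csv(index=False)
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None
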