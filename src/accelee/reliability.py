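"""Between-device / between-placement reliability statistics.

Two raters (two devices at one placement, or one device at two placements)
measure the same subject-bouts; reliability per treadmill speed and per MET
equation is summarised by the two-way mixed, consistency-type intraclass
correlation — ICC(3,1) single-measure and ICC(3,k) average-measure, from the
mean squares of a subjects × raters ANOVA — and by Cronbach's
standardized-items alpha, ``k·r̄ / (1 + (k−1)·r̄)`` with r̄ the mean pairwise
Pearson correlation among raters.  Negative ICC estimates are reported as
computed; they are legitimate outcomes of the consistency ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateInputError
from .equations import ALL_EQUATION_IDS, EEResult
from .signal_io import StudyManifest


@dataclass
class ICCResult:
    """Consistency ICCs and standardized alpha for one n×k rater matrix."""

    icc_single: float        # ICC(3,1), two-way mixed, consistency
    icc_average: float       # ICC(3,k)
    alpha_standardized: float
    n_subjects: int
    k_raters: int

    # alias matching the "consistency-type ICC" naming used in the docs
    @property
    def icc_consistency(self) -> float:
        return self.icc_single


def _validate_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise DataError(f"expected an n×k matrix, got shape {values.shape}")
    n, k = values.shape
    if n < 3:
        raise DataError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise DataError(f"need at least 2 raters, got {k}")
    if not np.all(np.isfinite(values)):
        raise DataError("matrix contains non-finite values")
    return values


def icc_two_way_mixed(values: np.ndarray) -> ICCResult:
    """Two-way mixed consistency ICC from ANOVA mean squares.

    ``ICC(3,1) = (MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error)``,
    ``ICC(3,k) = (MS_subjects − MS_error) / MS_subjects`` where MS_error is
    the subjects × raters interaction mean square (rater main effects removed,
    so systematic per-rater offsets do not penalise consistency).
    """
    values = _validate_matrix(values)
    n, k = values.shape
    grand = values.mean()
    if np.allclose(values, grand):
        raise DegenerateInputError("zero total variance: ICC undefined")
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_subjects = k * float(np.sum((row_means - grand) ** 2))
    ss_raters = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_error = ss_total - ss_subjects - ss_raters
    ms_subjects = ss_subjects / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    denom_single = ms_subjects + (k - 1) * ms_error
    if denom_single == 0:
        raise DegenerateInputError("degenerate ANOVA decomposition: ICC undefined")
    icc_single = (ms_subjects - ms_error) / denom_single
    # perfectly anti-correlated raters have MS_subjects = 0: the single-measure
    # form is -1 there while the average-measure form is undefined
    icc_average = ((ms_subjects - ms_error) / ms_subjects if ms_subjects > 0
                   else float("nan"))
    try:
        alpha = cronbach_alpha_standardized(values)
    except DegenerateInputError:
        alpha = float("nan")
    return ICCResult(icc_single=float(icc_single), icc_average=float(icc_average),
                     alpha_standardized=alpha, n_subjects=n, k_raters=k)


def cronbach_alpha_standardized(values: np.ndarray) -> float:
    """Standardized-items alpha from the mean pairwise Pearson correlation."""
    values = _validate_matrix(values)
    n, k = values.shape
    if np.any(np.std(values, axis=0) == 0):
        raise DegenerateInputError("a rater column has zero variance")
    corr = np.corrcoef(values, rowvar=False)
    r_bar = float(np.mean(corr[np.triu_indices(k, 1)]))
    return k * r_bar / (1.0 + (k - 1) * r_bar)


# ---------------------------------------------------------------------------
# Study-level agreement tables (speed × equation)
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """Speed × equation reliability table plus pairing diagnostics."""

    table: pd.DataFrame          # index: speeds + "MEAN"; cols: alpha_std + equations
    skipped: pd.DataFrame        # cells that could not be paired, with reasons
    contrast: str
    selector: str
    icc_form: str
    n_pairs_per_speed: dict[float, int] = field(default_factory=dict)


def paired_values(
    ee: Sequence[EEResult],
    manifest: StudyManifest,
    contrast: str,
    selector: str,
    *,
    configurations: Sequence[int] | None = None,
) -> tuple[dict[float, dict[str, np.ndarray]], pd.DataFrame]:
    """Pair rater measurements per (participant, configuration, speed) cell.

    ``contrast='device_at_placement'``: selector is a placement; raters are the
    two device families recorded there.  ``contrast='placement_within_device'``:
    selector is a device family; raters are its wrist and thigh placements.
    Returns {speed: {equation_id: n×2 matrix}} plus a skipped-cells report.
    """
    by_record = {r.record_id: r for r in ee}
    skipped: list[dict] = []
    cells: dict[tuple, dict[str, object]] = {}
    for rec in manifest:
        if configurations is not None and rec.configuration not in configurations:
            continue
        if contrast == "device_at_placement":
            if rec.placement != selector:
                continue
            rater = rec.device
        elif contrast == "placement_within_device":
            if rec.device != selector:
                continue
            rater = rec.placement
        else:
            raise DataError(f"unknown contrast {contrast!r}")
        key = (rec.participant_id, rec.configuration, rec.speed_kmh)
        cell = cells.setdefault(key, {})
        if rater in cell:
            skipped.append({"participant_id": key[0], "configuration": key[1],
                            "speed_kmh": key[2],
                            "reason": f"duplicate rater {rater!r}"})
            cell["__ambiguous__"] = True
            continue
        cell[rater] = rec.record_id

    per_speed: dict[float, dict[str, list[tuple[float, float]]]] = {}
    rater_order: dict[float, tuple[str, str]] = {}
    for (pid, conf, speed), cell in sorted(cells.items()):
        ambiguous = cell.pop("__ambiguous__", False)
        raters = sorted(cell)
        if ambiguous:
            continue
        if len(raters) != 2:
            skipped.append({"participant_id": pid, "configuration": conf,
                            "speed_kmh": speed,
                            "reason": f"unmatched pair (raters present: {raters})"})
            continue
        rid_a, rid_b = cell[raters[0]], cell[raters[1]]
        if rid_a not in by_record or rid_b not in by_record:
            missing = [r for r in (rid_a, rid_b) if r not in by_record]
            skipped.append({"participant_id": pid, "configuration": conf,
                            "speed_kmh": speed,
                            "reason": f"no EE result for {missing}"})
            continue
        rater_order.setdefault(speed, (raters[0], raters[1]))
        eq_map = per_speed.setdefault(speed, {eq: [] for eq in ALL_EQUATION_IDS})
        for eq in ALL_EQUATION_IDS:
            eq_map[eq].append((by_record[rid_a].mets[eq], by_record[rid_b].mets[eq]))

    matrices = {
        speed: {eq: np.asarray(pairs, dtype=float) for eq, pairs in eq_map.items()}
        for speed, eq_map in per_speed.items()
    }
    skipped_df = pd.DataFrame(skipped, columns=["participant_id", "configuration",
                                                "speed_kmh", "reason"])
    return matrices, skipped_df


def _pooled_alpha(eq_matrices: dict[str, np.ndarray]) -> float:
    """Per-speed standardized alpha over the two raters, pooling equations.

    Each equation's paired columns are z-scored (so equations on different
    MET scales weigh equally), rows are stacked, and alpha is computed on the
    pooled n·E × 2 matrix.  Equations whose columns are constant at this
    speed are left out of the pool.
    """
    blocks = []
    for m in eq_matrices.values():
        sd = m.std(axis=0)
        if np.any(sd == 0):
            continue
        blocks.append((m - m.mean(axis=0)) / sd)
    if not blocks:
        raise DegenerateInputError("no equation with variance at this speed")
    pooled = np.vstack(blocks)
    return cronbach_alpha_standardized(pooled)


def agreement_table(
    ee: Sequence[EEResult],
    manifest: StudyManifest,
    contrast: str,
    selector: str,
    *,
    icc_form: str = "single",
    configurations: Sequence[int] | None = None,
    min_pairs: int = 3,
) -> AgreementResult:
    """Speed × equation ICC table with a per-speed alpha column and a MEAN row."""
    if icc_form not in ("single", "average"):
        raise DataError(f"icc_form must be 'single' or 'average', got {icc_form!r}")
    matrices, skipped = paired_values(ee, manifest, contrast, selector,
                                      configurations=configurations)
    speeds = sorted(matrices)
    rows: dict[float, dict[str, float]] = {}
    n_pairs: dict[float, int] = {}
    for speed in speeds:
        eq_mats = matrices[speed]
        n = next(iter(eq_mats.values())).shape[0]
        n_pairs[speed] = n
        if n < min_pairs:
            continue
        row: dict[str, float] = {}
        try:
            row["alpha_std"] = _pooled_alpha(eq_mats)
        except DegenerateInputError:
            row["alpha_std"] = float("nan")
        for eq, m in eq_mats.items():
            try:
                res = icc_two_way_mixed(m)
                row[eq] = res.icc_single if icc_form == "single" else res.icc_average
            except (DataError, DegenerateInputError):
                row[eq] = float("nan")
        rows[speed] = row

    cols = ["alpha_std", *ALL_EQUATION_IDS]
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    table.index.name = "speed_kmh"
    table = table.sort_index()
    mean_row = table.mean(axis=0, skipna=True)
    table.index = table.index.astype(object)
    table.loc["MEAN"] = mean_row
    return AgreementResult(table=table, skipped=skipped, contrast=contrast,
                           selector=selector, icc_form=icc_form,
                           n_pairs_per_speed=n_pairs)


def write_agreement_csv(result: AgreementResult, path: str | Path) -> Path:
    path = Path(path)
    result.table.to_csv(path, float_format="%.6f", lineterminator="\r\n")
    return path


def write_agreement_tidy_csv(result: AgreementResult, path: str | Path) -> Path:
    """Long-format alternative: speed, statistic, value."""
    path = Path(path)
    tidy = (result.table.reset_index()
            .melt(id_vars="speed_kmh", var_name="statistic", value_name="value"))
    tidy.to_csv(path, index=False, float_format="%.6f", lineterminator="\r\n")
    return path
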