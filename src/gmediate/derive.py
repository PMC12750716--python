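"""Derivation of analysis variables from raw postpartum questionnaire responses.

The analysis works on four kinds of variables:

* **Exposure** ``x_helpful`` — whether the mother reports finding the clinic
  nurses helpful *always* (1) versus sometimes / seldom / never (0).
* **Mediator** ``bses_total`` — the Breastfeeding Self-Efficacy Scale, Short
  Form (BSES-SF): 14 Likert items scored 1-5 and summed to a 14-70 total,
  optionally dichotomised at a threshold (default 56) into ``m_bses_high``.
* **Outcome** ``y_exclusive`` — exclusive breastfeeding: currently
  breastfeeding *and* never having given the newborn anything besides
  breastmilk.
* **Confounders** — maternal age, infant age (days), parity, delivery mode,
  education, employment, HIV status, a 13-item household-asset count, and two
  Health Literacy Questionnaire (HLQ) scales ("feeling understood and
  supported by healthcare providers", HPS; "having sufficient information to
  manage health", HSI), each the mean of 4 items scored 1-4 and dichotomised
  at 2.5.

All derivations are deterministic and total on valid input; invalid input
raises :class:`ValidationError` naming the offending value.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BSES_N_ITEMS",
    "BSES_MIN",
    "BSES_MAX",
    "BSES_HIGH_THRESHOLD",
    "HLQ_N_ITEMS",
    "HLQ_HIGH_CUT",
    "N_ASSET_ITEMS",
    "HELPFULNESS_LEVELS",
    "binarize_exposure",
    "score_bses",
    "binarize_bses",
    "derive_exclusivity",
    "score_hlq_scale",
    "count_assets",
    "parse_bool",
    "derive_table",
]

BSES_N_ITEMS = 14
BSES_MIN = 14
BSES_MAX = 70
#: Dichotomisation threshold for the BSES-SF total; scores >= 56 are "high".
BSES_HIGH_THRESHOLD = 56
HLQ_N_ITEMS = 4
HLQ_HIGH_CUT = 2.5
N_ASSET_ITEMS = 13

HELPFULNESS_LEVELS = ("always", "sometimes", "seldom", "never")

_TRUE_STRINGS = {"1", "yes", "true"}
_FALSE_STRINGS = {"0", "no", "false"}


class ValidationError(ValueError):
    """Raised when a raw response fails a range or shape check."""


def binarize_exposure(nurse_helpful: str) -> int:
    """Collapse the ordinal nurse-helpfulness response to binary.

    ``always`` maps to 1; ``sometimes``, ``seldom`` and ``never`` map to 0.
    """
    level = str(nurse_helpful).strip().lower()
    if level not in HELPFULNESS_LEVELS:
        raise ValidationError(
            f"unknown helpfulness level {nurse_helpful!r}; "
            f"expected one of {HELPFULNESS_LEVELS}"
        )
    return 1 if level == "always" else 0


def score_bses(items: Sequence[int]) -> int:
    """Sum the 14 BSES-SF items (each 1-5) into the 14-70 total score."""
    items = list(items)
    if len(items) != BSES_N_ITEMS:
        raise ValidationError(
            f"BSES-SF requires exactly {BSES_N_ITEMS} items, got {len(items)}"
        )
    for i, v in enumerate(items, start=1):
        if not float(v).is_integer() or not 1 <= int(v) <= 5:
            raise ValidationError(f"BSES-SF item {i} out of range [1,5]: {v!r}")
    return int(sum(int(v) for v in items))


def binarize_bses(total: int, threshold: int = BSES_HIGH_THRESHOLD) -> int:
    """Dichotomise the BSES-SF total: 1 ("high") iff ``total >= threshold``."""
    if not BSES_MIN <= total <= BSES_MAX:
        raise ValidationError(
            f"BSES-SF total {total!r} outside [{BSES_MIN},{BSES_MAX}]"
        )
    return 1 if total >= threshold else 0


def derive_exclusivity(
    currently_breastfeeding: bool, ever_given_other: bool
) -> int:
    """Exclusive breastfeeding: currently breastfeeding and never given
    anything besides breastmilk."""
    return 1 if (currently_breastfeeding and not ever_given_other) else 0


def score_hlq_scale(
    items: Sequence[int], cut: float = HLQ_HIGH_CUT
) -> tuple[float, int]:
    """Score one 4-item HLQ scale.

    Returns ``(mean, high)`` where ``mean`` is the item mean on [1,4] and
    ``high`` is 1 iff ``mean >= cut``.
    """
    items = list(items)
    if len(items) != HLQ_N_ITEMS:
        raise ValidationError(
            f"HLQ scale requires exactly {HLQ_N_ITEMS} items, got {len(items)}"
        )
    for i, v in enumerate(items, start=1):
        if not float(v).is_integer() or not 1 <= int(v) <= 4:
            raise ValidationError(f"HLQ item {i} out of range [1,4]: {v!r}")
    mean = float(np.mean([int(v) for v in items]))
    return mean, int(mean >= cut)


def count_assets(items: Sequence[bool]) -> int:
    """Count owned items on the 13-item household-asset checklist."""
    items = list(items)
    if len(items) != N_ASSET_ITEMS:
        raise ValidationError(
            f"asset checklist requires exactly {N_ASSET_ITEMS} items, "
            f"got {len(items)}"
        )
    return int(sum(bool(v) for v in items))


def parse_bool(value) -> bool:
    """Parse a boolean cell; accepts 0/1, yes/no, true/false (any case)."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if float(value) in (0.0, 1.0):
            return bool(value)
        raise ValidationError(f"cannot interpret {value!r} as boolean")
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


# ---------------------------------------------------------------------------
# table-level derivation

#: analysis columns that trigger listwise exclusion when missing
ANALYSIS_COLUMNS = ("x_helpful", "bses_total", "m_bses_high", "y_exclusive")

DEFAULT_CONFOUNDERS = (
    "age",
    "infant_age",
    "parity",
    "caesarean",
    "educ_grade12",
    "employed",
    "hiv",
    "assets",
    "hps_high",
    "hsi_high",
)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        pd.isna(value) if np.isscalar(value) or value is None else False
    )


def derive_table(
    raw: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    confounders: Iterable[str] = DEFAULT_CONFOUNDERS,
    bses_threshold: int = BSES_HIGH_THRESHOLD,
    hlq_cut: float = HLQ_HIGH_CUT,
) -> tuple[pd.DataFrame, dict]:
    """Derive the analysis table from raw (or partially pre-derived) data.

    Per column: if a derived column (``x_helpful``, ``bses_total``,
    ``m_bses_high``, ``y_exclusive``, ``hps_high``, ``hsi_high``, ``assets``)
    is already present it is used as-is; otherwise it is derived from the raw
    item columns (``nurse_helpful``; ``bses_item_1`` .. ``bses_item_14``;
    ``currently_breastfeeding`` + ``ever_given_other``; ``hlq_hps_1`` ..;
    ``hlq_hsi_1`` ..; ``asset_1`` .. ``asset_13``).

    Records missing the exposure, mediator, outcome or any requested
    confounder are excluded listwise.  Repeat-visit records whose collection
    day equals the first visit's day (column ``visit_day``, when present, per
    participant ``pid``) are excluded.

    Returns ``(derived, exclusion_log)`` where ``exclusion_log`` counts
    exclusions per reason.
    """
    column_map = dict(column_map or {})
    df = raw.rename(columns={v: k for k, v in column_map.items()}).copy()
    log: dict = {"n_input": int(len(df)), "reasons": {}}

    def _count(reason: str, n: int) -> None:
        if n:
            log["reasons"][reason] = log["reasons"].get(reason, 0) + int(n)

    # --- exposure -----------------------------------------------------------
    if "x_helpful" not in df.columns:
        if "nurse_helpful" not in df.columns:
            raise ValidationError(
                "need either 'x_helpful' or raw 'nurse_helpful' column"
            )
        df["x_helpful"] = [
            np.nan if pd.isna(v) else binarize_exposure(v)
            for v in df["nurse_helpful"]
        ]

    # --- mediator -----------------------------------------------------------
    if "bses_total" not in df.columns:
        item_cols = [f"bses_item_{i}" for i in range(1, BSES_N_ITEMS + 1)]
        missing_cols = [c for c in item_cols if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"missing BSES item columns: {missing_cols}")
        totals = []
        for _, row in df[item_cols].iterrows():
            if row.isna().any():
                totals.append(np.nan)
            else:
                totals.append(score_bses(row.tolist()))
        df["bses_total"] = totals
    if "m_bses_high" not in df.columns:
        df["m_bses_high"] = [
            np.nan if pd.isna(t) else binarize_bses(int(t), bses_threshold)
            for t in df["bses_total"]
        ]

    # --- outcome ------------------------------------------------------------
    if "y_exclusive" not in df.columns:
        for c in ("currently_breastfeeding", "ever_given_other"):
            if c not in df.columns:
                raise ValidationError(f"missing raw feeding column {c!r}")
        ys = []
        for cb, eo in zip(df["currently_breastfeeding"], df["ever_given_other"]):
            if pd.isna(cb) or pd.isna(eo):
                ys.append(np.nan)
            else:
                ys.append(derive_exclusivity(parse_bool(cb), parse_bool(eo)))
        df["y_exclusive"] = ys

    # --- HLQ scales and assets ---------------------------------------------
    for scale, derived_col in (("hps", "hps_high"), ("hsi", "hsi_high")):
        if derived_col in df.columns:
            continue
        item_cols = [f"hlq_{scale}_{i}" for i in range(1, HLQ_N_ITEMS + 1)]
        if not all(c in df.columns for c in item_cols):
            continue  # scale not collected; caller may not use it
        highs = []
        for _, row in df[item_cols].iterrows():
            if row.isna().any():
                highs.append(np.nan)
            else:
                highs.append(score_hlq_scale(row.tolist(), hlq_cut)[1])
        df[derived_col] = highs

    if "assets" not in df.columns:
        item_cols = [f"asset_{i}" for i in range(1, N_ASSET_ITEMS + 1)]
        if all(c in df.columns for c in item_cols):
            counts = []
            for _, row in df[item_cols].iterrows():
                if row.isna().any():
                    counts.append(np.nan)
                else:
                    counts.append(count_assets([parse_bool(v) for v in row]))
            df["assets"] = counts

    # --- repeat-visit rule --------------------------------------------------
    if "visit" in df.columns and "visit_day" in df.columns and "pid" in df.columns:
        first_day = (
            df[df["visit"] == "first"].set_index("pid")["visit_day"].to_dict()
        )
        same_day = df.apply(
            lambda r: r["visit"] == "repeat"
            and r["pid"] in first_day
            and r["visit_day"] == first_day[r["pid"]],
            axis=1,
        )
        _count("repeat_visit_same_day", same_day.sum())
        df = df[~same_day]

    # --- listwise exclusion on missing analysis variables -------------------
    confounders = [c for c in confounders if c in df.columns]
    required = list(ANALYSIS_COLUMNS) + confounders
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"analysis column {col!r} absent after derivation")
    missing_mask = df[required].isna().any(axis=1)
    for col in required:
        _count(f"missing_{col}", (df[col].isna() & ~df[required].drop(columns=col).isna().any(axis=1)).sum())
    _count("missing_any_analysis_column", missing_mask.sum())
    df = df[~missing_mask].copy()

    for col in ("x_helpful", "m_bses_high", "y_exclusive"):
        df[col] = df[col].astype(int)
    df["bses_total"] = df["bses_total"].astype(int)

    log["n_excluded"] = log["n_input"] - int(len(df))
    log["n_analysis"] = int(len(df))
    return df.reset_index(drop=True), log
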