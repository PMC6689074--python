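"""Agreement between in silico predicted affinity, in vitro relative binding
and in vivo expression calls across construct variants.

Measured relative binding is accepted as user-quantified band intensities or
ordinal grades; only the ordering enters the rank statistic, so any strictly
monotone quantification convention gives the same result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats


class AnalysisError(ValueError):
    """Insufficient or misaligned comparison data."""


@dataclass
class VariantRecord:
    """One construct variant with its per-factor and per-segment channels."""

    name: str
    predicted_affinity: dict[str, float] = field(default_factory=dict)  # factor -> value
    measured_binding: dict[str, float] = field(default_factory=dict)  # factor -> value
    observed_expression: dict[str, str] = field(default_factory=dict)  # segment -> call


def rank_concordance(records: list[VariantRecord], factor: str) -> float:
    """Kendall rank correlation (tau-b) between predicted and measured
    relative binding for one factor across variants."""
    pairs = [
        (r.predicted_affinity[factor], r.measured_binding[factor])
        for r in records
        if factor in r.predicted_affinity and factor in r.measured_binding
    ]
    if len(pairs) < 2:
        raise AnalysisError(
            f"need >= 2 variants with both channels for factor {factor!r}, got {len(pairs)}"
        )
    predicted, measured = zip(*pairs)
    tau = stats.kendalltau(predicted, measured, variant="b").statistic
    return float(tau)


def expression_agreement(
    records: list[VariantRecord],
    predictions: dict[str, dict[str, str]],
) -> tuple[float, pd.DataFrame]:
    """Fraction of (variant, segment) cells where the predicted ternary call
    matches the observed call, with the full confusion table attached.

    ``predictions`` maps variant name -> {segment: call}.
    """
    observed_calls, predicted_calls = [], []
    for record in records:
        if record.name not in predictions:
            continue
        pred = predictions[record.name]
        for segment, observed in record.observed_expression.items():
            if segment in pred:
                observed_calls.append(observed)
                predicted_calls.append(pred[segment])
    if not observed_calls:
        raise AnalysisError("no overlapping (variant, segment) cells to compare")
    confusion = pd.crosstab(
        pd.Series(observed_calls, name="observed"),
        pd.Series(predicted_calls, name="predicted"),
    )
    matches = sum(o == p for o, p in zip(observed_calls, predicted_calls))
    return matches / len(observed_calls), confusion


def records_from_table(table: pd.DataFrame) -> list[VariantRecord]:
    """Build records from a tidy table with columns
    (variant, key, channel, value) where channel is one of
    predicted / measured / expression."""
    records: dict[str, VariantRecord] = {}
    for _, row in table.iterrows():
        rec = records.setdefault(row["variant"], VariantRecord(row["variant"]))
        if row["channel"] == "predicted":
            rec.predicted_affinity[row["key"]] = float(row["value"])
        elif row["channel"] == "measured":
            rec.measured_binding[row["key"]] = float(row["value"])
        elif row["channel"] == "expression":
            rec.observed_expression[row["key"]] = str(row["value"])
        else:
            raise AnalysisError(f"unknown channel {row['channel']!r}")
    return list(records.values())
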