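"""The molecular risk score.

The score counts, per tumor, the molecular risk factors
{absence of CTNNB1 mutation, presence of TP53 mutation, high FAL,
global hypomethylation}.  In the four-factor mode (transplant setting) a
count >= 3 marks the "aggressive" molecular pattern; the three-factor
variant (array cohorts where repeat-element methylation is unavailable)
drops global hypomethylation and uses >= 2.  TERT-promoter mutation and
TSG-promoter hypermethylation never contribute: both are frequent from
the earliest tumor stages and carry no aggressiveness signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

FOUR_FACTOR_ORDER = ("ctnnb1_wildtype", "tp53_mutant", "fal_high", "global_hypo")
THREE_FACTOR_ORDER = ("ctnnb1_wildtype", "tp53_mutant", "fal_high")

_DEFAULT_AGGRESSIVE_MIN = {"four_factor": 3, "three_factor": 2}


@dataclass(frozen=True)
class RiskScore:
    mode: str
    factors_present: frozenset[str]
    count: int
    pattern: str  # "aggressive" | "mild"


def compute_risk_score(
    ctnnb1_mut: bool,
    tp53_mut: bool,
    fal_high: bool,
    global_hypo: bool | None = None,
    mode: str = "four_factor",
    aggressive_min: int | None = None,
) -> RiskScore:
    """Risk-factor count and aggressive/mild pattern for one tumor.

    ``global_hypo`` may be omitted only in three-factor mode.
    """
    if mode not in _DEFAULT_AGGRESSIVE_MIN:
        raise ValueError(f"unknown mode {mode!r}")
    cut = _DEFAULT_AGGRESSIVE_MIN[mode] if aggressive_min is None else aggressive_min
    factors = set()
    if not ctnnb1_mut:
        factors.add("ctnnb1_wildtype")
    if tp53_mut:
        factors.add("tp53_mutant")
    if fal_high:
        factors.add("fal_high")
    if mode == "four_factor":
        if global_hypo is None or (isinstance(global_hypo, float) and pd.isna(global_hypo)):
            raise ValueError("four_factor mode requires a defined global_hypo flag")
        if global_hypo:
            factors.add("global_hypo")
    count = len(factors)
    pattern = "aggressive" if count >= cut else "mild"
    return RiskScore(mode=mode, factors_present=frozenset(factors),
                     count=count, pattern=pattern)


class MolecularRiskScorer(TransformerMixin, BaseEstimator):
    """Stateless transformer from the feature table to per-sample risk scores.

    ``transform`` takes the per-sample feature table (boolean columns
    ``ctnnb1_mut``, ``tp53_mut``, ``fal_high`` and, in four-factor mode,
    ``global_hypo``) and returns one row per sample with the individual
    factor indicators, the count and the aggressive/mild pattern.
    """

    def __init__(self, mode: str = "four_factor", aggressive_min: int | None = None):
        self.mode = mode
        self.aggressive_min = aggressive_min

    def fit(self, X=None, y=None):
        if self.mode not in _DEFAULT_AGGRESSIVE_MIN:
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        features = pd.DataFrame(X)
        order = FOUR_FACTOR_ORDER if self.mode == "four_factor" else THREE_FACTOR_ORDER
        rows = []
        for sample_id, row in features.iterrows():
            try:
                score = compute_risk_score(
                    bool(row["ctnnb1_mut"]), bool(row["tp53_mut"]), bool(row["fal_high"]),
                    global_hypo=row.get("global_hypo"),
                    mode=self.mode, aggressive_min=self.aggressive_min,
                )
            except ValueError as exc:
                raise ValueError(f"sample {sample_id!r}: {exc}") from exc
            rec = {f: (f in score.factors_present) for f in order}
            rec["count"] = score.count
            rec["pattern"] = score.pattern
            rows.append(rec)
        out = pd.DataFrame(rows, index=features.index,
                           columns=list(order) + ["count", "pattern"])
        out.index.name = "sample_id"
        return out


def score_cohort(features: pd.DataFrame, mode: str = "four_factor",
                 aggressive_min: int | None = None) -> pd.DataFrame:
    """Score every sample; returns the per-sample factor/count/pattern table."""
    scores = MolecularRiskScorer(mode=mode, aggressive_min=aggressive_min).transform(features)
    if len(scores):
        counts = scores["pattern"].value_counts().to_dict()
        import logging
        logging.getLogger(__name__).info("risk patterns: %s", counts)
    return scores
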