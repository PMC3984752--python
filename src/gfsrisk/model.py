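"""Model/Results front end for the genetic fuzzy risk-stratification system.

`UARiskModel` is constructed from a labelled cohort and fuzzy-partitioning /
GA settings; ``fit()`` derives the fuzzy partitions, mines the per-class
rule base, and returns a `UARiskResults` carrying the rules with their
support/confidence/fitness, prediction methods, diagnostics, and a
``summary()`` table.

    >>> model = UARiskModel(table1_fixture(), ga_config=GAConfig(seed=7))
    >>> res = model.fit()
    >>> print(res.summary())                       # doctest: +SKIP
    >>> res.predict(new_cases)                     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Prediction, RuleBase, predict_batch
from .data import (
    Dataset,
    FeatureSchema,
    PatientCase,
    RiskLabel,
    RISK_LEVELS,
    class_counts,
)
from .evaluate import EvalReport, agreement, confusion, cross_validate, sensitivity, specificity
from .ga import GAConfig, mine_all
from .partition import FuzzyPartition, partition_all
from .rules import RuleSpace, rule_to_text


def dataset_from_dataframe(
    df: pd.DataFrame,
    schema: Sequence[FeatureSchema],
    label_column: str = "risk",
    id_column: str = "id",
) -> Dataset:
    """Build a validated Dataset from a pandas DataFrame."""
    cases = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        case_id = str(row[id_column]) if id_column in df.columns else f"case_{i}"
        values = {}
        for feat in schema:
            if feat.name not in df.columns:
                continue
            v = row[feat.name]
            if pd.isna(v):
                values[feat.name] = None
            elif feat.is_numerical:
                values[feat.name] = float(v)
            else:
                values[feat.name] = str(v)
        label = None
        if label_column in df.columns and not pd.isna(row[label_column]):
            label = RiskLabel.parse(str(row[label_column]))
        cases.append(PatientCase(case_id, values, label))
    schema_copy = [
        FeatureSchema(f.name, f.kind, None if f.is_numerical else list(f.domain))
        for f in schema
    ]
    return Dataset(schema_copy, cases)


class UARiskModel:
    """Genetic fuzzy system for three-level unstable-angina risk.

    Parameters
    ----------
    data : Dataset
        Labelled training cohort.
    epsilon : float, mapping, optional
        Merge threshold(s) for the fuzzy partitioning of numerical features;
        defaults to 0.15 x the observed range per feature.
    ga_config : GAConfig, optional
        Genetic-algorithm settings (population, generations, rates, seed).
    fallback : RiskLabel or "majority"
        Class predicted when no rule fires.
    """

    def __init__(
        self,
        data: Dataset,
        epsilon: float | Mapping[str, float] | None = None,
        ga_config: GAConfig | None = None,
        fallback: RiskLabel | str = RiskLabel.MEDIUM,
    ) -> None:
        if len(data) < 1:
            raise ValueError("empty training cohort")
        self.data = data
        self.epsilon = epsilon
        self.ga_config = ga_config or GAConfig()
        self.fallback = fallback

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: Sequence[FeatureSchema],
        label_column: str = "risk",
        **kwargs,
    ) -> "UARiskModel":
        return cls(dataset_from_dataframe(df, schema, label_column), **kwargs)

    def fit(self, seed: int | None = None) -> "UARiskResults":
        """Partition the numerical features, mine the rule base, return results."""
        cfg = self.ga_config if seed is None else replace(self.ga_config, seed=seed)
        partitions = partition_all(self.data, epsilon=self.epsilon)
        rule_base = mine_all(self.data, partitions, cfg, fallback=self.fallback)
        return UARiskResults(self, rule_base, partitions, cfg)

    def cross_validate(
        self, folds: int = 10, rounds: int = 10, seed: int = 0
    ) -> EvalReport:
        """Rounds of stratified k-fold CV of the full fit/predict pipeline."""
        return cross_validate(
            self.data, epsilon=self.epsilon, ga_config=self.ga_config,
            folds=folds, rounds=rounds, seed=seed,
        )


class UARiskResults:
    """Fitted rule base plus diagnostics and prediction methods."""

    def __init__(
        self,
        model: UARiskModel,
        rule_base: RuleBase,
        partitions: dict[str, FuzzyPartition],
        config: GAConfig,
    ) -> None:
        self.model = model
        self.rule_base = rule_base
        self.partitions = partitions
        self.config = config
        self.space = RuleSpace(model.data.schema, partitions)

    # -- prediction --------------------------------------------------------

    def predict(self, data: Dataset | pd.DataFrame) -> list[Prediction]:
        if isinstance(data, pd.DataFrame):
            data = dataset_from_dataframe(data, self.model.data.schema)
        return predict_batch(self.rule_base, data)

    def predictions_frame(self, data: Dataset | pd.DataFrame) -> pd.DataFrame:
        """Per-case scores and predicted level as a DataFrame."""
        preds = self.predict(data)
        return pd.DataFrame(
            {
                "id": [p.case_id for p in preds],
                "v_low": [p.scores.v_low for p in preds],
                "v_medium": [p.scores.v_medium for p in preds],
                "v_high": [p.scores.v_high for p in preds],
                "predicted": [p.label.level for p in preds],
                "no_rule_fired": [p.no_rule_fired for p in preds],
            }
        )

    # -- diagnostics -------------------------------------------------------

    def rules_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rule_base.rules:
            rows.append(
                {
                    "class": r.consequent.level,
                    "n_features": r.n_features,
                    "support": r.stats.get("support"),
                    "confidence": r.stats.get("confidence"),
                    "fitness": r.stats.get("fitness"),
                    "rule": rule_to_text(r, self.space),
                }
            )
        return pd.DataFrame(rows)

    def training_report(self) -> EvalReport:
        """Resubstitution metrics of the fitted base on its training cohort."""
        preds = [p.label for p in self.predict(self.model.data)]
        truth = self.model.data.labels()
        cc = confusion(preds, truth)
        count, frac = agreement(preds, truth)
        return EvalReport(
            mode="resubstitution",
            confusion=cc,
            sensitivity={c: sensitivity(cc, c) for c in RISK_LEVELS},
            specificity={c: specificity(cc, c) for c in RISK_LEVELS},
            agreement_count=count,
            agreement_fraction=frac,
            n_evaluated=len(truth),
        )

    def summary(self) -> str:
        """Human-readable fit summary: cohort, partitions, mined rules."""
        d = self.model.data
        counts = class_counts(d)
        lines = [
            "Unstable-angina genetic fuzzy risk model",
            "=" * 72,
            f"Cases: {len(d)}   "
            + "  ".join(f"{c.level}: {counts[c]}" for c in RISK_LEVELS),
            f"Features: {len(d.schema)} "
            f"({sum(f.is_numerical for f in d.schema)} numerical, "
            f"{sum(not f.is_numerical for f in d.schema)} categorical)",
            f"GA: pop {self.config.population_size}, "
            f"gens {self.config.generations}, "
            f"cx {self.config.crossover_rate}, mut {self.config.mutation_rate}, "
            f"seed {self.config.seed}",
            "",
            "Fuzzy partitions",
            "-" * 72,
        ]
        for name, p in self.partitions.items():
            mids = ", ".join(f"{m:g}" for m in p.midpoints)
            lines.append(
                f"{name}: [{p.v0:g}, {p.vmax:g}] midpoints [{mids}] "
                f"-> {p.n_sets} sets ({', '.join(p.labels)})"
            )
        lines += ["", "Mined rules", "-" * 72]
        for cls in RISK_LEVELS:
            section = self.rule_base.by_class(cls)
            lines.append(f"{cls.level}: {len(section)} rules")
            for r in section:
                lines.append(
                    f"  S={r.stats['support']:.3f} C={r.stats['confidence']:.3f} "
                    f"F={r.stats['fitness']:.3f}  {rule_to_text(r, self.space)}"
                )
        rep = self.training_report()
        lines += [
            "",
            f"Training agreement: {rep.agreement_count}/{rep.n_evaluated} "
            f"({rep.agreement_fraction:.1%})",
        ]
        return "\n".join(lines)

    def plot_partitions(self, features: Sequence[str] | None = None, ax=None):
        """Plot the triangular membership functions per numerical feature."""
        import matplotlib.pyplot as plt

        names = list(features or self.partitions)
        fig, axes = plt.subplots(len(names), 1, figsize=(6, 2.2 * len(names)),
                                 squeeze=False)
        for axis, name in zip(axes[:, 0], names):
            p = self.partitions[name]
            xs = np.linspace(p.v0, p.vmax, 400)
            for j in range(p.n_sets):
                axis.plot(xs, p.membership(j, xs), label=p.labels[j])
            axis.set_title(name)
            axis.legend(fontsize=7)
        fig.tight_layout()
        return fig
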