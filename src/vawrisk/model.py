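"""Model / Results interface over the classification pipeline.

:class:`MunicipalRiskModel` bundles a set of municipality records with a
sorter configuration; :meth:`~MunicipalRiskModel.fit` runs normalisation,
composite-index construction and ELECTRE TRI-B sorting and returns a
:class:`MunicipalRiskResults` carrying the assignments, the exclusions,
sensitivity diagnostics and tabular/graphical reporting.

Example
-------
>>> from vawrisk import MunicipalRiskModel, simulate
>>> records = simulate.generate_municipalities(simulate.GeneratorParams(seed=1))
>>> res = MunicipalRiskModel.from_records(records).fit()
>>> res.class_distribution().to_frame()  # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import reporting
from .electre import AssignmentResult, ModelConfig, classify_all, default_config
from .io import (MunicipalRecord, PerformanceTable, build_performance_table,
                 frame_to_records, read_municipal_csv)
from .sensitivity import StabilityReport, lambda_sweep, weight_perturbation


class MunicipalRiskModel:
    """Multicriteria risk-sorting model for a set of municipalities.

    Parameters
    ----------
    records
        Municipality indicator records (see :class:`~vawrisk.io.MunicipalRecord`).
    config
        Sorter configuration; defaults to the published study configuration
        (four criteria, five limit profiles, lambda = 0.60).
    bounds
        Optional fixed normalisation bounds per criterion code; by default
        min/max are taken from the dataset itself.
    """

    def __init__(self, records: Sequence[MunicipalRecord],
                 config: ModelConfig | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None):
        self.records = list(records)
        self.config = config if config is not None else default_config()
        self.bounds = bounds
        self._table: PerformanceTable | None = None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, config: ModelConfig | None = None,
                 **kwargs) -> "MunicipalRiskModel":
        """Build the model from the canonical indicator CSV."""
        return cls(read_municipal_csv(path), config=config, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: ModelConfig | None = None,
                       **kwargs) -> "MunicipalRiskModel":
        """Build the model from a DataFrame with the canonical columns."""
        return cls(frame_to_records(df), config=config, **kwargs)

    @classmethod
    def from_records(cls, records: Sequence[MunicipalRecord],
                     config: ModelConfig | None = None,
                     **kwargs) -> "MunicipalRiskModel":
        return cls(records, config=config, **kwargs)

    # -- fitting ------------------------------------------------------

    @property
    def performance_table(self) -> PerformanceTable:
        """The normalised alternatives x criteria matrix (built lazily)."""
        if self._table is None:
            self._table = build_performance_table(self.records,
                                                  bounds=self.bounds)
        return self._table

    def fit(self) -> "MunicipalRiskResults":
        """Sort every classifiable municipality into a risk category."""
        table = self.performance_table
        assignments = classify_all(table, self.config)
        return MunicipalRiskResults(self, table, assignments)


class MunicipalRiskResults:
    """Fitted classification: assignments, exclusions and diagnostics."""

    def __init__(self, model: MunicipalRiskModel, table: PerformanceTable,
                 assignments: list[AssignmentResult]):
        self.model = model
        self.table = table
        self.assignments = assignments

    # -- core accessors ----------------------------------------------

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    @property
    def excluded(self) -> dict[str, str]:
        return self.table.excluded

    @property
    def n_classified(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        """Assignment table with excluded municipalities explicitly marked."""
        return reporting.assignments_to_frame(
            self.assignments, excluded=self.excluded, names=self.table.names)

    # -- reporting ----------------------------------------------------

    def class_distribution(self,
                           rule: str = "pessimistic") -> reporting.ClassDistribution:
        return reporting.class_distribution(self.assignments, rule=rule)

    def complaints_by_class(self, rule: str = "pessimistic") -> pd.DataFrame:
        return reporting.complaints_by_class(self.assignments,
                                             self.model.records, rule=rule)

    def export_geojson(self, geometry, out_path=None, key: str = "id") -> dict:
        return reporting.export_geojson(self.assignments, geometry,
                                        out_path=out_path, key=key)

    # -- sensitivity ---------------------------------------------------

    def sensitivity_lambda(self, delta: float = 0.05) -> StabilityReport:
        """Re-sort under lambda +/- delta; count class changes."""
        return lambda_sweep(self.table, self.config, delta=delta)

    def sensitivity_weights(self) -> StabilityReport:
        """Re-sort with each criterion weight at 1.00 and the rest at 0.50."""
        return weight_perturbation(self.table, self.config)

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (classification counts per category)."""
        cfg = self.config
        lines = [
            "Municipal risk classification (ELECTRE TRI-B)",
            "=" * 46,
            f"Municipalities:      {len(self.model.records)}",
            f"Classified:          {self.n_classified}",
            f"Excluded:            {len(self.excluded)}",
            f"Criteria:            {', '.join(cfg.codes)}",
            f"Limit profiles:      {cfg.n_profiles} "
            f"({cfg.n_classes} ordered categories)",
            f"Lambda cut:          {cfg.lambda_cut:.2f}",
            "",
            "Class distribution (pessimistic rule)",
            "-" * 46,
        ]
        dist = self.class_distribution()
        for k in sorted(dist.counts, reverse=True):
            label = dist.labels.get(k, str(k))
            lines.append(f"  class {k}  {label:<15} {dist.counts[k]:>5}")
        lines.append("-" * 46)
        lines.append(f"  total                    {dist.total:>5}")
        for alt_id, reason in self.excluded.items():
            name = self.table.names.get(alt_id, alt_id)
            lines.append(f"  excluded: {name} ({reason})")
        return "\n".join(lines)

    def plot_distribution(self, ax=None, rule: str = "pessimistic"):
        """Bar chart of municipalities per risk category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.class_distribution(rule=rule).to_frame()
        ax.bar(frame["label"], frame["count"])
        ax.set_xlabel("risk category")
        ax.set_ylabel("municipalities")
        ax.tick_params(axis="x", rotation=45)
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MunicipalRiskResults: {self.n_classified} classified, "
                f"{len(self.excluded)} excluded, "
                f"lambda={self.config.lambda_cut:.2f}>")
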