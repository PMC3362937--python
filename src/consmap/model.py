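"""Model-style front end: :class:`ConsensusMapper` and its results object.

`ConsensusMapper` holds a consensus problem (datasets, RF matrices,
weights) together with the pipeline configuration; :meth:`ConsensusMapper.fit`
runs the two-phase analysis and returns a :class:`ConsensusMapResults`
carrying the consensus solution, the cost-of-consensus diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core import ConsensusProblem, ConsensusSolution, Dataset, conflict_free
from .exceptions import ValidationError
from .ges import GESParams
from .pipeline import (
    PipelineConfig,
    RunResult,
    build_integral_map,
    recovery_coefficient,
    run_consensus,
    suggest_removals,
)
from .twopoint import build_rf_matrix

__all__ = ["ConsensusMapper", "ConsensusMapResults"]


class ConsensusMapper:
    """Consensus linkage-map model over several mapping populations.

    Parameters
    ----------
    problem : ConsensusProblem
        Datasets with their RF matrices and weights.
    config : PipelineConfig, optional
        Pipeline settings; keyword arguments override individual fields,
        e.g. ``ConsensusMapper(problem, weights_mode="inverse_length")``.
    """

    def __init__(
        self,
        problem: ConsensusProblem,
        config: PipelineConfig | None = None,
        **config_overrides,
    ):
        self.problem = problem
        cfg = config or PipelineConfig()
        if config_overrides:
            ges_kwargs = {
                k: config_overrides.pop(k)
                for k in list(config_overrides)
                if hasattr(GESParams(), k) and not hasattr(cfg, k)
            }
            cfg = replace(cfg, **config_overrides)
            if ges_kwargs:
                cfg.ges = replace(cfg.ges, **ges_kwargs)
        self.config = cfg

    @classmethod
    def from_datasets(
        cls,
        datasets: list[Dataset],
        weights: list[float] | None = None,
        min_informative: int = 10,
        **config_overrides,
    ) -> "ConsensusMapper":
        """Build the model from raw datasets, estimating RF matrices."""
        rfms = [build_rf_matrix(ds, min_informative=min_informative) for ds in datasets]
        return cls(ConsensusProblem(datasets, rfms, weights), **config_overrides)

    @classmethod
    def from_manifest(cls, path, **config_overrides) -> "ConsensusMapper":
        from .io import read_manifest

        return cls(read_manifest(path), **config_overrides)

    def fit(
        self, method: str = "both", seed: int | None = None
    ) -> "ConsensusMapResults":
        """Run phase 1 + phase 2 and return the fitted results.

        ``method``: ``"local"`` (conflict regions only), ``"global"``
        (whole-chromosome GES) or ``"both"``.
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        result = run_consensus(self.problem, cfg, method=method)
        return ConsensusMapResults(self, result, method)


class ConsensusMapResults:
    """Fitted consensus map: solution, diagnostics, reporting."""

    def __init__(self, model: ConsensusMapper, result: RunResult, method: str):
        self.model = model
        self.result = result
        self.method = method

    # -- principal outputs ----------------------------------------------
    @property
    def solution(self) -> ConsensusSolution:
        return self.result.solution

    @property
    def shared_order(self) -> tuple[str, ...]:
        return self.result.solution.shared_order.sequence

    @property
    def S_total(self) -> float:
        return self.result.solution.S_total

    @property
    def cost_report(self):
        return self.result.cost_report

    @property
    def conflict_free(self) -> bool:
        return conflict_free(self.result.solution)

    @property
    def n_conflicts_detected(self) -> int:
        return len(self.result.conflicts)

    # -- diagnostics -----------------------------------------------------
    def recovery(self, true_shared_order) -> float:
        """Recovery coefficient of the consensus shared order against the
        simulated true order (simulation runs only)."""
        if hasattr(true_shared_order, "true_shared_order"):
            true_shared_order = true_shared_order.true_shared_order
        return recovery_coefficient(
            self.result.solution.shared_order, true_shared_order
        )

    def integral_map(self):
        """The integral map as a :class:`networkx.DiGraph` (see
        :func:`consmap.pipeline.build_integral_map`)."""
        return build_integral_map(self.result.solution, self.model.problem)

    def suggest_removals(self, **kwargs):
        return suggest_removals(
            self.model.problem, self.result, self.model.config, **kwargs
        )

    def summary(self) -> str:
        """Human-readable per-dataset table plus run-level diagnostics."""
        res = self.result
        lines = []
        lines.append("Consensus linkage map (two-phase synchronized ordering)")
        lines.append("=" * 62)
        lines.append(
            f"datasets: {len(res.filtered_maps)}   shared markers: "
            f"{len(res.shared_markers)}   method: {self.method}"
        )
        lines.append(
            f"conflicts detected: {len(res.conflicts)}   "
            f"regions: {len(res.regions)}   conflict-free: {self.conflict_free}"
        )
        lines.append(f"criterion S_total: {self.S_total:.4f}")
        lines.append("-" * 62)
        lines.append(
            f"{'set':>3} {'type':>4} {'markers':>8} {'Ind(cM)':>9} "
            f"{'Cons(cM)':>9} {'delta':>7} {'weight':>8}"
        )
        for ds, dc, w in zip(
            self.model.problem.datasets, res.cost_report.per_dataset, res.weights
        ):
            flag = " *" if dc.high_cost else ""
            lines.append(
                f"{ds.id:>3} {ds.cross_type.value:>4} "
                f"{len(res.filtered_maps[ds.id].order):>8} "
                f"{dc.L_ind_cM:>9.1f} {dc.L_cons_cM:>9.1f} "
                f"{dc.delta_cM:>7.1f} {w:>8.4g}{flag}"
            )
        if res.cost_report.high_cost_datasets():
            lines.append(
                "* cost of consensus above "
                f"{res.cost_report.threshold_cM:g} cM: consider "
                "suggest_removals()"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ConsensusMapResults: {len(self.shared_order)} shared markers, "
            f"S_total={self.S_total:.4f}, conflict_free={self.conflict_free}>"
        )
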