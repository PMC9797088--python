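"""Model/Results interface tying the pipeline together.

:class:`DecisionNetworkModel` couples a fitted tree ensemble with its
training data; :meth:`~DecisionNetworkModel.fit` runs
extract → discretize → prune → stability-select → aggregate and returns a
:class:`DecisionNetworkResults` carrying the stable decision ensemble, the
feature/interaction importance and influence estimates with their bootstrap
selection probabilities, the decision network, and a ``summary()`` table.

    >>> model = DecisionNetworkModel(spec, data)
    >>> res = model.fit(n_levels=2, stability=StabilityParams(B=10))
    >>> print(res.summary())
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .decisions import extract_decisions, group_duplicate_rules
from .metrics import aggregate_metrics
from .model_io import (
    CLASSIFICATION,
    Dataset,
    TreeEnsembleSpec,
    make_dataset,
    read_feature_table,
    read_tree_dump,
    validate_model_against_data,
)
from .network import (
    DecisionNetwork,
    build_network,
    export_network,
    importance_influence_table,
    reduce_network,
)
from .regularize import (
    DiscretizationMap,
    StabilityParams,
    StableEnsemble,
    discretize,
    prune_decisions,
    stability_select,
    trivial_stable,
)

logger = logging.getLogger(__name__)


class DecisionNetworkModel:
    """A fitted tree ensemble bound to its training data, ready to interpret."""

    def __init__(self, model: TreeEnsembleSpec, data: Dataset):
        validate_model_against_data(model, data)
        self.model = model
        self.data = data

    @classmethod
    def from_files(
        cls,
        model_path,
        data_path,
        dialect: str = "node-csv",
        response_column: str = "y",
        task: str = CLASSIFICATION,
        positive_class: Optional[str] = None,
    ) -> "DecisionNetworkModel":
        data = read_feature_table(
            data_path, response_column, task, positive_class
        )
        model = read_tree_dump(model_path, dialect, task=task)
        return cls(model, data)

    @classmethod
    def from_dataframe(
        cls, X: pd.DataFrame, y, model: TreeEnsembleSpec,
        task: str = CLASSIFICATION,
    ) -> "DecisionNetworkModel":
        return cls(model, make_dataset(X, y, task))

    def fit(
        self,
        n_levels: Optional[int] = 2,
        discretization: str = "data",
        prune_tolerance: Optional[float] = 0.05,
        stability: Union[StabilityParams, None, str] = "default",
        seed: Optional[int] = None,
    ) -> "DecisionNetworkResults":
        """Run the interpretation pipeline.

        ``n_levels=None`` skips discretization, ``prune_tolerance=None``
        skips pruning, ``stability=None`` skips bootstrap selection (every
        regularized decision is kept).  When stability selection is on,
        pruning runs *inside* each bootstrap resample (decision-wise
        regularization is part of the resampled computation); otherwise it
        runs once on the full data.  ``seed`` overrides the stability seed.
        """
        counts = {}
        ensemble = extract_decisions(self.model, self.data)
        counts["extracted"] = len(ensemble)
        ensemble = group_duplicate_rules(ensemble)
        counts["grouped"] = len(ensemble)

        dmap: Optional[DiscretizationMap] = None
        work_data = self.data
        if n_levels is not None:
            work_data, dmap, ensemble = discretize(
                self.data, ensemble, K=n_levels, method=discretization
            )
            counts["discretized"] = len(ensemble)

        if stability == "default":
            stability = StabilityParams()
        if stability is None:
            if prune_tolerance is not None:
                ensemble = prune_decisions(ensemble, work_data, prune_tolerance)
                counts["pruned"] = len(ensemble)
            stable = trivial_stable(ensemble)
        else:
            if seed is not None:
                stability = dataclasses.replace(stability, seed=seed)
            stable = stability_select(
                work_data, ensemble, stability, prune_tolerance=prune_tolerance
            )
        counts["stable"] = len(stable)
        logger.info("pipeline counts: %s", counts)
        return DecisionNetworkResults(
            model=self,
            stable=stable,
            disc_map=dmap,
            counts=counts,
            params={
                "n_levels": n_levels,
                "discretization": discretization if n_levels else None,
                "prune_tolerance": prune_tolerance,
                "stability": (
                    dataclasses.asdict(stability) if stability else None
                ),
            },
        )


@dataclass
class DecisionNetworkResults:
    """Estimates from an interpretation run.

    Attributes of interest: ``decisions`` (stable decision table with
    selection probabilities and averaged importances), ``feature_metrics``
    and ``interaction_metrics`` (variable-level F and Γ), ``network`` (the
    pseudo-feature decision network), ``summary()``.
    """

    model: DecisionNetworkModel
    stable: StableEnsemble
    disc_map: Optional[DiscretizationMap]
    counts: dict
    params: dict
    _network: Optional[DecisionNetwork] = field(default=None, repr=False)
    _aggregates: Optional[tuple] = field(default=None, repr=False)

    @property
    def disc_features(self) -> set:
        return self.disc_map.features if self.disc_map else set()

    @property
    def n_stable(self) -> int:
        return len(self.stable)

    @property
    def decisions(self) -> pd.DataFrame:
        return self.stable.to_frame()

    def _aggregate(self):
        if self._aggregates is None:
            dm = self.stable.pool_metrics
            keep = self.stable.stable_mask()
            dm = dataclasses.replace(dm, present=dm.present & keep)
            self._aggregates = aggregate_metrics(self.stable.pool, dm)
        return self._aggregates

    @property
    def feature_metrics(self) -> pd.DataFrame:
        return self._aggregate()[0].table

    @property
    def interaction_metrics(self) -> pd.DataFrame:
        return self._aggregate()[1].table

    @property
    def feature_influence(self) -> dict:
        return dict(
            zip(self.feature_metrics["feature"], self.feature_metrics["influence"])
        )

    @property
    def network(self) -> DecisionNetwork:
        if self._network is None:
            self._network = build_network(
                self.stable,
                disc_features=self.disc_features,
                provenance={"model_fingerprint": self.model.model.fingerprint()},
            )
        return self._network

    def reduced_network(self, max_path: int = 3) -> DecisionNetwork:
        return reduce_network(self.network, max_path=max_path)

    def importance_influence_table(self) -> pd.DataFrame:
        return importance_influence_table(self.stable, self.disc_features)

    def summary(self, top: int = 10) -> str:
        data = self.model.data
        lines = [
            "Decision network interpretation",
            "=" * 47,
            f"task: {data.task}   n = {data.n}   p = {data.p}   "
            f"trees = {self.model.model.n_trees}",
            "decision counts: "
            + " -> ".join(f"{k} {v}" for k, v in self.counts.items()),
            f"stability: q = {self.stable.q}, mean decisions per resample = "
            f"{self.stable.d_mean:.1f}, pi_thr = {self.stable.params.pi_thr}, "
            f"alpha = {self.stable.params.alpha_reg}, B = {self.stable.params.B}",
            "",
            f"Top features (importance F, influence Gamma)",
            "-" * 47,
        ]
        ftab = self.feature_metrics.sort_values(
            "importance", ascending=False
        ).head(top)
        lines.append(ftab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        itab = self.interaction_metrics.sort_values(
            "importance", ascending=False
        ).head(top)
        if len(itab):
            lines += ["", "Top interactions", "-" * 47,
                      itab.to_string(index=False,
                                     float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------

    def manifest(self) -> dict:
        return {
            "task": self.model.data.task,
            "n": self.model.data.n,
            "p": self.model.data.p,
            "n_trees": self.model.model.n_trees,
            "model_fingerprint": self.model.model.fingerprint(),
            "params": self.params,
            "counts": self.counts,
            "q": self.stable.q,
            "d_mean": self.stable.d_mean,
        }

    def save(self, outdir) -> dict:
        """Write decision/metric TSVs, the network, and a run manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "decisions": os.path.join(outdir, "decisions.tsv"),
            "feature_metrics": os.path.join(outdir, "feature_metrics.tsv"),
            "interaction_metrics": os.path.join(
                outdir, "interaction_metrics.tsv"
            ),
            "importance_influence": os.path.join(
                outdir, "importance_influence.tsv"
            ),
            "graphml": os.path.join(outdir, "network.graphml"),
            "nodes": os.path.join(outdir, "network_nodes.tsv"),
            "edges": os.path.join(outdir, "network_edges.tsv"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        self.decisions.to_csv(
            paths["decisions"], sep="\t", index=False, float_format="%.10g"
        )
        self.feature_metrics.to_csv(
            paths["feature_metrics"], sep="\t", index=False, float_format="%.10g"
        )
        self.interaction_metrics.to_csv(
            paths["interaction_metrics"], sep="\t", index=False,
            float_format="%.10g",
        )
        self.importance_influence_table().to_csv(
            paths["importance_influence"], sep="\t", index=False,
            float_format="%.10g",
        )
        export_network(
            self.network,
            graphml_path=paths["graphml"],
            nodes_tsv=paths["nodes"],
            edges_tsv=paths["edges"],
        )
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    # ------------------------------------------------------------------
    # plotting (thin optional layer; correctness lives in the exports)
    # ------------------------------------------------------------------

    def plot_network(self, ax=None, reduced: bool = False, max_path: int = 3):
        from .plotting import plot_network

        net = self.reduced_network(max_path) if reduced else self.network
        return plot_network(net, ax=ax)

    def plot_importance_influence(self, ax=None, top: int = 20):
        from .plotting import plot_importance_influence

        return plot_importance_influence(
            self.importance_influence_table(), ax=ax, top=top
        )
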