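"""Model/Results facade over the full two-step procedure.

:class:`ResponseProcessModel` holds the data (action patterns) and the
analysis settings (similarity measure, threshold κ); :meth:`fit` runs
pairwise similarity → graph construction → exact cluster edge deletion
and returns a :class:`ResponseProcessResults` carrying the clustering,
its objective and diagnostics, with clique summaries and the
idiosyncrasy contrast hanging off it.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import Clustering, solve_cluster_deletion, verify_cluster_graph
from .graph import SimilarityGraph, build_graph, write_graphml
from .patterns import ActionPattern, patterns_from_log, write_patterns
from .similarity import (
    SimilarityMeasureSpec,
    pairwise_similarities,
    write_edge_list,
)
from .summaries import (
    CliqueSummary,
    idiosyncrasy_report,
    summarize_clustering,
    write_summaries,
)

__all__ = ["ResponseProcessModel", "ResponseProcessResults"]


class ResponseProcessModel:
    """Identify common response processes in time-stamped action sequences.

    Parameters
    ----------
    patterns
        The action patterns to cluster.
    measure
        Similarity measure: ``"original"`` (per-action min–max timing),
        ``"modified"`` (aggregate timing over the overlap; default) or
        ``"action_only"`` (timing ignored).
    kappa
        Similarity threshold in (0, 1] for including an edge in the
        graph; default 0.5 (a medium similarity suffices to allow two
        patterns into one clique).
    """

    def __init__(
        self,
        patterns: Sequence[ActionPattern],
        measure: str = "modified",
        kappa: float = 0.5,
    ):
        if len(patterns) == 0:
            raise ValueError("no action patterns supplied")
        self.patterns = list(patterns)
        self.measure = SimilarityMeasureSpec(measure)
        if not (0.0 < kappa <= 1.0):
            raise ValueError(f"kappa must lie in (0, 1], got {kappa}")
        self.kappa = float(kappa)

    @classmethod
    def from_dataframe(
        cls,
        rows: pd.DataFrame,
        measure: str = "modified",
        kappa: float = 0.5,
        time_mode: str = "times_to_action",
        item_onset: float | Mapping = 0.0,
    ) -> "ResponseProcessModel":
        """Build from a long event log (person_id, action, time columns)."""
        pats = patterns_from_log(rows, time_mode=time_mode, item_onset=item_onset)
        return cls(pats, measure=measure, kappa=kappa)

    def fit(self, time_limit: float = 3600.0) -> "ResponseProcessResults":
        """Compute all pairwise similarities, threshold, and solve the ILP."""
        edges = pairwise_similarities(self.patterns, self.measure)
        graph = build_graph(
            edges, kappa=self.kappa, vertices=[p.person_id for p in self.patterns]
        )
        clustering = solve_cluster_deletion(graph, time_limit=time_limit)
        assert verify_cluster_graph(graph, clustering)
        return ResponseProcessResults(self, edges, graph, clustering)


class ResponseProcessResults:
    """Fitted clustering plus diagnostics and reporting."""

    def __init__(
        self,
        model: ResponseProcessModel,
        edges: pd.DataFrame,
        graph: SimilarityGraph,
        clustering: Clustering,
    ):
        self.model = model
        self.edges = edges
        self.graph = graph
        self.clustering = clustering

    # ------------------------------------------------------ reporting ----

    @property
    def membership(self) -> dict:
        return self.clustering.membership

    def clique_summaries(self) -> list[CliqueSummary]:
        return summarize_clustering(self.clustering, self.model.patterns)

    def clique_summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.clique_summaries():
            d = s.__dict__.copy()
            d["common_lcs"] = " ".join(s.common_lcs)
            rows.append(d)
        return pd.DataFrame(rows)

    def idiosyncrasy_report(self, min_dominant_size: int = 5) -> pd.DataFrame:
        return idiosyncrasy_report(
            self.clustering, self.model.patterns, min_dominant_size
        )

    def summary(self) -> str:
        """Plain-text overview in the spirit of a model-results table."""
        c = self.clustering
        g = self.graph
        sizes = sorted((len(cl) for cl in c.cliques), reverse=True)
        lines = [
            "Response Process Clustering (cluster edge deletion)",
            "=" * 55,
            f"measure:            {self.model.measure.kind}",
            f"kappa:              {self.model.kappa:g}",
            f"patterns (N):       {len(self.model.patterns)}",
            f"input edges:        {g.number_of_edges()}",
            f"deleted edges:      {len(c.deleted_edges)}"
            + (
                f" ({100 * len(c.deleted_edges) / g.number_of_edges():.2f}%)"
                if g.number_of_edges()
                else ""
            ),
            f"retained weight:    {c.objective:.4f}",
            f"cliques:            {c.n_cliques}",
            f"singleton cliques:  {len(c.singletons())}",
            f"clique sizes:       {sizes}",
            f"solver status:      {c.status} ({c.solver}, "
            f"{c.wall_time:.2f}s)",
        ]
        return "\n".join(lines)

    # --------------------------------------------------------- export ----

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full artifact bundle; returns name → path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "patterns": outdir / "patterns.csv",
            "edges": outdir / "edges.tsv",
            "graph": outdir / "graph.graphml",
            "membership": outdir / "membership.csv",
            "deleted_edges": outdir / "deleted_edges.tsv",
            "summaries": outdir / "clique_summaries.csv",
            "idiosyncrasy": outdir / "idiosyncrasy.csv",
            "metadata": outdir / "run_metadata.json",
        }
        write_patterns(self.model.patterns, paths["patterns"])
        write_edge_list(self.edges, paths["edges"])
        write_graphml(self.graph, paths["graph"])
        memb = self.membership
        pd.DataFrame(
            {
                "person_id": [p.person_id for p in self.model.patterns],
                "clique_id": [memb[p.person_id] for p in self.model.patterns],
            }
        ).to_csv(paths["membership"], index=False)
        pd.DataFrame(
            [sorted(map(str, e)) for e in sorted(
                self.clustering.deleted_edges, key=lambda e: sorted(map(str, e))
            )],
            columns=["i", "j"],
        ).to_csv(paths["deleted_edges"], sep="\t", index=False)
        write_summaries(self.clique_summaries(), paths["summaries"])
        self.idiosyncrasy_report().to_csv(paths["idiosyncrasy"])
        meta = {
            "version": __version__,
            "measure": self.model.measure.kind,
            "kappa": self.model.kappa,
            "n_patterns": len(self.model.patterns),
            "n_edges": self.graph.number_of_edges(),
            "n_deleted": len(self.clustering.deleted_edges),
            "objective": self.clustering.objective,
            "n_cliques": self.clustering.n_cliques,
            "status": self.clustering.status,
            "solver": self.clustering.solver,
            "wall_time_s": self.clustering.wall_time,
        }
        paths["metadata"].write_text(json.dumps(meta, indent=2))
        return paths
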