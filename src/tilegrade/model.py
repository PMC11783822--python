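"""Model/results front for the Tile grading causal network.

``TileBayesModel`` wraps a boolean patient table and a network structure;
``fit()`` performs Bayesian CPD estimation and returns ``TileBayesResults``,
which carries the fitted tables and exposes posterior queries, grading,
fracture retrieval and a clinician-auditable ``summary()``.
"""

from __future__ import annotations

from typing import AbstractSet, Mapping, Optional, Sequence

import pandas as pd

from .bayes import (
    CPDSet,
    Inference,
    NetworkSpec,
    TileGrade,
    default_structure,
    fit_cpds,
    model_to_dict,
    save_model,
)
from .fusion import Thresholds
from .records import FractureType, PatientRecord
from .refinement import RefinementResult, initial_grade, refine


class TileBayesModel:
    """Boolean causal network model of pelvic-fracture instability.

    Parameters
    ----------
    data : DataFrame with one 0/1 column per network node, one row per
        labeled patient.
    spec : network structure; defaults to the expert graph
        (age60 -> R,T; R,T -> each fracture type).
    pseudocount : Laplace smoothing strength for CPD estimation.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: Optional[NetworkSpec] = None,
        pseudocount: float = 1.0,
    ) -> None:
        self.spec = spec or default_structure()
        missing = [n for n in self.spec.nodes if n not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns for nodes: {missing}")
        self.data = data[list(self.spec.nodes)].astype(int)
        self.pseudocount = float(pseudocount)

    @classmethod
    def from_patients(
        cls,
        patients: Sequence[PatientRecord],
        spec: Optional[NetworkSpec] = None,
        pseudocount: float = 1.0,
    ) -> "TileBayesModel":
        """Build the training table from labeled patient records."""
        from .evaluation import _truth_frame

        return cls(_truth_frame(patients), spec, pseudocount)

    def fit(self) -> "TileBayesResults":
        cpds = fit_cpds(self.spec, self.data, self.pseudocount)
        return TileBayesResults(self, cpds)


class TileBayesResults:
    """Fitted CPDs plus the inference, grading and retrieval surface."""

    def __init__(self, model: TileBayesModel, cpds: CPDSet) -> None:
        self.model = model
        self.spec = model.spec
        self.cpds = cpds
        self._engine = Inference(self.spec, cpds)

    # -- inference ---------------------------------------------------------

    def marginal(self, evidence: Mapping[str, bool], query: str) -> float:
        """Exact posterior P(query=1 | evidence)."""
        return self._engine.marginal(evidence, query)

    def grade(
        self, fx_high: AbstractSet[FractureType], age60: Optional[bool]
    ) -> tuple[float, float, TileGrade]:
        """Initial Tile grade from the high-confidence findings."""
        return initial_grade(self.spec, self.cpds, fx_high, age60, self._engine)

    def refine(
        self,
        fx_high: AbstractSet[FractureType],
        fx_low: AbstractSet[FractureType],
        age60: Optional[bool],
        thresholds: Thresholds = Thresholds(),
    ) -> RefinementResult:
        """Bayesian retrieval of likely-missed low-confidence findings."""
        return refine(self.spec, self.cpds, fx_high, fx_low, age60, thresholds, self._engine)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Readable CPD tables, for clinical audit."""
        lines = [
            "Tile grading causal network",
            "=" * 60,
            f"nodes: {len(self.spec.nodes)}   edges: {len(self.spec.edges)}   "
            f"n_patients: {len(self.model.data)}   pseudocount: {self.model.pseudocount}",
            "",
        ]
        d = model_to_dict(self.spec, self.cpds)
        for node, entry in d["cpds"].items():
            header = f"P({node}=1 | {', '.join(entry['parents'])})" if entry["parents"] else f"P({node}=1)"
            lines.append(header)
            for cfg, p in entry["p_node_is_1"].items():
                lines.append(f"  {cfg:<40s} {p:.4f}")
            lines.append("")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self.spec, self.cpds, path)
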