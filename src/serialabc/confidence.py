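"""Confidence in scenario choice via pseudo-observed datasets (PODs).

For each candidate scenario, datasets are simulated from its prior and
classified against an existing reference table by highest posterior
probability.  The tallies give a confusion matrix from which type I error
(the true scenario does not win) and type II error (a scenario wins when it
is not the true one) are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abc import ReferenceTable, scenario_posteriors
from .coalescent import dataset_summaries
from .scenarios import sample_prior

__all__ = ["ConfusionMatrix", "run_pods"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of inferred (columns) vs simulating (rows) scenarios."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) ints
    n_pods: int

    def __post_init__(self):
        if not np.all(self.counts.sum(axis=1) == self.n_pods):
            raise ValueError("every row must sum to the number of PODs")

    def type_i(self) -> dict[str, float]:
        """Per scenario: fraction of its own PODs not assigned to it."""
        diag = np.diag(self.counts)
        return {
            lab: float(1.0 - diag[i] / self.n_pods)
            for i, lab in enumerate(self.labels)
        }

    def type_ii(self) -> dict[str, float]:
        """Pooled: fraction of PODs from *other* scenarios assigned here."""
        k = len(self.labels)
        out = {}
        for j, lab in enumerate(self.labels):
            wrong = self.counts[:, j].sum() - self.counts[j, j]
            out[lab] = float(wrong / ((k - 1) * self.n_pods))
        return out

    def type_ii_conditional(self) -> dict[str, float]:
        """Conditional: of datasets assigned to a scenario, the fraction
        whose true scenario was different."""
        out = {}
        for j, lab in enumerate(self.labels):
            assigned = self.counts[:, j].sum()
            if assigned == 0:
                out[lab] = 0.0
            else:
                out[lab] = float(
                    (assigned - self.counts[j, j]) / assigned
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=list(self.labels), columns=list(self.labels)
        )
        df.index.name = "true_scenario"
        return df


def run_pods(
    table: ReferenceTable,
    n_pods_per_scenario: int,
    rng: np.random.Generator,
    tolerance: float = 0.01,
    use_logistic: bool = True,
) -> ConfusionMatrix:
    """Classify PODs from each scenario's prior against the reference table.

    PODs are classified against the full, already-built table (nothing is
    held out); with tables of thousands of rows per scenario the chance that
    a POD's own near-duplicate sits in the table is negligible.
    """
    labels = tuple(table.scenarios)
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for i, name in enumerate(labels):
        scn = table.scenarios[name]
        for _ in range(n_pods_per_scenario):
            draw = sample_prior(scn, rng, n_loci=table.sample_config.n_loci)
            s = dataset_summaries(draw, table.sample_config, rng)
            post = scenario_posteriors(table, s, tolerance)
            best = post.best(
                table.scenarios, use="logistic" if use_logistic else "direct"
            )
            counts[i, labels.index(best)] += 1
    return ConfusionMatrix(labels=labels, counts=counts, n_pods=n_pods_per_scenario)
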