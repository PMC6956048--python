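"""Synthetic qPCR Ct tables with a stable housekeeping gene.

Under the standard exponential-amplification model a gene expressed
``2**effect``-fold above baseline crosses threshold ``effect`` cycles earlier,
so Ct(sample, gene) = baseline_ct(gene) - log2_effect(group, gene) + noise.
The housekeeping gene has effect 0 in every group by construction, which is
what makes it usable for normalization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CtTableParams", "generate_ct_table"]


@dataclass(frozen=True)
class CtTableParams:
    """Design of the expression experiment: groups, genes, effects, noise."""

    genes: Sequence[str]
    groups: Sequence[str]
    housekeeping: str = "Gapdh"
    control_group: str = "control"
    #: (group, gene) -> log2 fold change vs the control group; missing = 0
    log2_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    baseline_ct: Mapping[str, float] = field(default_factory=dict)
    replicates_per_group: int = 6
    ct_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.housekeeping not in self.genes:
            raise ValueError(
                f"housekeeping gene {self.housekeeping!r} missing from genes {list(self.genes)}"
            )
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        for (grp, gene), eff in self.log2_effects.items():
            if gene == self.housekeeping and eff != 0.0:
                raise ValueError(
                    f"housekeeping gene {gene!r} must have log2 effect 0 in every "
                    f"group (got {eff} in {grp!r})"
                )


def generate_ct_table(params: CtTableParams) -> pd.DataFrame:
    """Simulate a long-form Ct table (sample_id, group, gene, ct).

    Deterministic for a fixed seed; exactly ``replicates_per_group`` samples
    per group, each measured for every gene.
    """
    rng = np.random.default_rng(params.seed)
    default_ct = 22.0
    rows = []
    for group in params.groups:
        for rep in range(params.replicates_per_group):
            sample_id = f"{group}_{rep + 1}"
            for gene in params.genes:
                ct = float(params.baseline_ct.get(gene, default_ct))
                ct -= float(params.log2_effects.get((group, gene), 0.0))
                if params.ct_noise_sd > 0:
                    ct += rng.normal(0.0, params.ct_noise_sd)
                rows.append((sample_id, group, gene, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
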