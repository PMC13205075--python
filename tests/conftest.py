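"""Shared fixtures: small synthetic experiments and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cernascreen.types import ExpressionMatrix, SimulationConfig
from cernascreen import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


SMALL_SIM = dict(
    n_mrna=80,
    n_lncrna=30,
    n_mirna=25,
    n_circrna=30,
    n_de_per_class={"mRNA": 16, "lncRNA": 8, "miRNA": 8, "circRNA": 8},
    n_triads=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_experiment():
    """One small complete experiment (counts, annotation, sequences, terms, truth)."""
    return synthetic.simulate_experiment(SimulationConfig(**SMALL_SIM))


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-feature x 4-sample matrix with unit size factors."""
    counts = pd.DataFrame(
        {
            "control_1": [10, 100, 6, 50],
            "control_2": [12, 90, 4, 50],
            "cold_1": [11, 110, 5, 50],
            "cold_2": [9, 95, 5, 50],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    rna_class = pd.Series(
        ["mRNA", "mRNA", "miRNA", "lncRNA"], index=counts.index
    )
    group = pd.Series(
        ["control", "control", "cold", "cold"], index=counts.columns
    )
    return ExpressionMatrix(counts=counts, rna_class=rna_class, group=group)


def naive_seed_scan(mirna_seq: str, target_seq: str) -> list[tuple[int, str]]:
    """Independent brute-force sliding-window site scanner (test oracle).

    Applies the four canonical definitions literally at every target
    position; returns (site_start, site_type) sorted by core position.
    """
    comp = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}
    core = "".join(comp[c] for c in mirna_seq[1:7])[::-1]
    m8 = comp[mirna_seq[7]]
    out = []
    for p in range(len(target_seq) - 5):
        if target_seq[p : p + 6] != core:
            continue
        has_m8 = p >= 1 and target_seq[p - 1] == m8
        has_a1 = p + 6 < len(target_seq) and target_seq[p + 6] == "A"
        if has_m8 and has_a1:
            out.append((p - 1, "8mer"))
        elif has_m8:
            out.append((p - 1, "7mer-m8"))
        elif has_a1:
            out.append((p, "7mer-A1"))
        else:
            out.append((p, "6mer"))
    return out


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
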