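"""Shared fixtures: synthetic inputs and one full demo-pipeline run."""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
import pytest

from octargets import pipeline, synthetic_data as sd
from octargets.datatypes import ExpressionDataset


@pytest.fixture(scope="session")
def sim_cfg() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on synthetic inputs (seed 1)."""
    root = tmp_path_factory.mktemp("demo")
    t0 = time.time()
    manifest = pipeline.run_demo(root, seed=1)
    elapsed = time.time() - t0
    return {
        "root": root,
        "inputs": root / "inputs",
        "run": root / "run",
        "manifest": manifest,
        "elapsed": elapsed,
        "truth": sd.GroundTruth.from_json(root / "inputs" / "ground_truth.json"),
    }


@pytest.fixture(scope="session")
def demo_run_repeat(tmp_path_factory):
    """Second, independent run with the same seed (reproducibility checks)."""
    root = tmp_path_factory.mktemp("demo_repeat")
    pipeline.run_demo(root, seed=1)
    return {"root": root, "run": root / "run"}


def make_dataset(values: np.ndarray, n_cancer: int, n_control: int,
                 batches=None, genes=None) -> ExpressionDataset:
    """Small helper to wrap a matrix into an ExpressionDataset."""
    g, n = values.shape
    assert n == n_cancer + n_control
    genes = genes or [f"g{i:04d}" for i in range(g)]
    samples = [f"s{i:03d}" for i in range(n)]
    cond = pd.Series(["cancer"] * n_cancer + ["control"] * n_control, index=samples)
    if batches is None:
        batches = ["b1"] * n
    batch = pd.Series(list(batches), index=samples)
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples),
                             cond, batch)


@pytest.fixture(scope="session")
def planted_shift_ds():
    """Two batches, planted logFC 1.0 on the first 50 of 500 genes, batch-2
    shift +2: the parameter-recovery scenario for batch correction."""
    rng = np.random.default_rng(42)
    g = 500
    base = rng.normal(7, 1.5, g)
    halves = []
    for shift in (0.0, 2.0):
        n_c, n_n = 15, 15
        X = base[:, None] + rng.normal(0, 0.25, (g, n_c + n_n))
        X[:50, :n_c] += 1.0  # planted DE, cancer samples first
        halves.append(X + shift)
    values = np.hstack(halves)
    samples = [f"s{i:03d}" for i in range(60)]
    cond = pd.Series((["cancer"] * 15 + ["control"] * 15) * 2, index=samples)
    batch = pd.Series(["b1"] * 30 + ["b2"] * 30, index=samples)
    return ExpressionDataset(
        pd.DataFrame(values, index=[f"g{i:04d}" for i in range(g)], columns=samples),
        cond, batch)
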