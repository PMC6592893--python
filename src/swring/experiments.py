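"""Headline experiments and result tables.

* :func:`theory_curves` -- closed-form observables on a beta grid (degree
  variance, two-stars, triangles, clustering, circulant spectrum, mixing
  time), one CSV-ready row per beta.
* :func:`run_pafpt_experiment` -- ensemble comparison of the pair-averaged
  first passage time (PAFPT) between the distance-based model, the original
  Watts-Strogatz rewiring model at the mapped rewiring probability, and
  optionally G(N, k/(N-1)); each realization is reduced to its largest
  component before the exact all-pairs MFPT solve.
* metadata sidecars recording parameters, seeds and the package version so
  every emitted table can be replayed bit-exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    clustering_coefficient,
    degree_variance,
    expected_triangles,
    expected_two_stars,
)
from .generate import sample_gnp, sample_small_world, sample_watts_strogatz
from .params import ModelParams, connection_probabilities, ws_rewiring_probability
from .walk import (
    gamma_factor,
    largest_component,
    mixing_time,
    pair_averaged_fpt,
    second_eigenvalue,
)

PathLike = Union[str, os.PathLike]

MODIFIED = "modified"
WS = "ws"
ER = "er"


def default_beta_grid(n_points: int = 12) -> np.ndarray:
    """Log-spaced beta grid over [1e-4, 1] plus the beta=0 endpoint."""
    return np.concatenate([[0.0], np.logspace(-4, 0, n_points - 1)])


def theory_curves(n: int, k: int, beta_grid: Sequence[float]) -> pd.DataFrame:
    """Closed-form observable table: one row per beta.

    Columns: beta, p_S, p_L, var_k, two_stars, triangles, clustering,
    Gamma, omega_1, t_mix.
    """
    rows = []
    for beta in beta_grid:
        params = ModelParams(n, k, float(beta))
        probs = connection_probabilities(params)
        rows.append(
            {
                "beta": float(beta),
                "p_S": probs.p_s,
                "p_L": probs.p_l,
                "var_k": degree_variance(params),
                "two_stars": expected_two_stars(params),
                "triangles": expected_triangles(params),
                "clustering": clustering_coefficient(params),
                "Gamma": gamma_factor(n, k),
                "omega_1": second_eigenvalue(params),
                "t_mix": mixing_time(params),
            }
        )
    return pd.DataFrame(rows)


def mixing_curves(n: int, k: int, beta_grid: Sequence[float]) -> pd.DataFrame:
    """Spectral table: beta, Gamma, omega_1, t_mix per row."""
    return theory_curves(n, k, beta_grid)[["beta", "Gamma", "omega_1", "t_mix"]]


@dataclass
class ExperimentResult:
    """Per-(beta, model) ensemble PAFPT means with replay information."""

    n: int
    k: int
    reps: int
    seed: int
    models: tuple[str, ...]
    table: pd.DataFrame
    p_r_by_beta: dict[float, float] = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "tool": "swring",
            "version": __version__,
            "experiment": "pafpt",
            "n": self.n,
            "k": self.k,
            "reps": self.reps,
            "seed": self.seed,
            "models": list(self.models),
            "p_r_by_beta": {str(b): p for b, p in self.p_r_by_beta.items()},
        }


def _sample_for_model(model: str, params: ModelParams, p_r: float, rng):
    if model == MODIFIED:
        return sample_small_world(params, rng)
    if model == WS:
        return sample_watts_strogatz(params.n, params.k, p_r, rng)
    if model == ER:
        return sample_gnp(params.n, params.k / (params.n - 1), rng)
    raise ValueError(f"unknown model {model!r}; choose from modified, ws, er")


def run_pafpt_experiment(
    n: int,
    k: int,
    beta_grid: Sequence[float],
    reps: int,
    seed: int,
    models: Sequence[str] = (MODIFIED, WS),
) -> ExperimentResult:
    """Ensemble PAFPT comparison across models on a beta grid.

    For every beta and model, ``reps`` independent graphs are sampled (the
    WS comparator at the mapped rewiring probability p_r(beta); the ER
    reference at p = k/(N-1), beta-independent); each is reduced to its
    largest component and its exact PAFPT computed.  The result table
    carries the ensemble mean, standard error, realization count and mean
    component size per cell, plus the relative difference
    (mean_WS - mean_modified) / mean_modified where both models are run.

    Cells whose largest component has fewer than 2 nodes are skipped and
    counted in ``n_skipped``.  Per-cell substreams are spawned
    deterministically from ``seed``, so (parameters, seed) replays
    bit-exactly.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    root = np.random.SeedSequence(seed)
    rows = []
    p_r_by_beta: dict[float, float] = {}
    for bi, beta in enumerate(beta_grid):
        params = ModelParams(n, k, float(beta))
        p_r = ws_rewiring_probability(params)
        p_r_by_beta[float(beta)] = p_r
        for mi, model in enumerate(models):
            # one substream per cell, keyed by (beta index, model index)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(bi, mi))
            )
            pafpts = []
            sizes = []
            n_skipped = 0
            for _ in range(reps):
                g = _sample_for_model(model, params, p_r, rng)
                comp = largest_component(g)
                if comp.number_of_nodes() < 2:
                    n_skipped += 1
                    continue
                pafpts.append(pair_averaged_fpt(comp))
                sizes.append(comp.number_of_nodes())
            pafpts = np.asarray(pafpts)
            rows.append(
                {
                    "beta": float(beta),
                    "model": model,
                    "p_r": p_r if model == WS else np.nan,
                    "mean_pafpt": pafpts.mean() if pafpts.size else np.nan,
                    "se_pafpt": (
                        pafpts.std(ddof=1) / np.sqrt(pafpts.size)
                        if pafpts.size > 1
                        else np.nan
                    ),
                    "n_reps": int(pafpts.size),
                    "n_skipped": n_skipped,
                    "mean_component_size": np.mean(sizes) if sizes else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    if MODIFIED in models and WS in models:
        rel = []
        for beta in table["beta"].unique():
            sub = table[table["beta"] == beta].set_index("model")
            rel.append(
                {
                    "beta": beta,
                    "rel_diff_ws_vs_modified": (
                        sub.loc[WS, "mean_pafpt"] - sub.loc[MODIFIED, "mean_pafpt"]
                    )
                    / sub.loc[MODIFIED, "mean_pafpt"],
                }
            )
        table = table.merge(pd.DataFrame(rel), on="beta", how="left")
    return ExperimentResult(
        n=n,
        k=k,
        reps=reps,
        seed=seed,
        models=tuple(models),
        table=table,
        p_r_by_beta=p_r_by_beta,
    )


def sidecar_path(path: PathLike) -> str:
    return f"{os.fspath(path)}.meta.json"


def write_run_metadata(path: PathLike, metadata: dict) -> str:
    """Write the JSON sidecar accompanying an emitted table or graph."""
    meta = dict(metadata)
    meta.setdefault("tool", "swring")
    meta.setdefault("version", __version__)
    out = sidecar_path(path)
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_run_metadata(path: PathLike) -> dict:
    """Read the sidecar for ``path``; error if it is missing (no replay)."""
    out = sidecar_path(path)
    if not os.path.exists(out):
        raise FileNotFoundError(
            f"no metadata sidecar {out!r}; the run cannot be replayed"
        )
    with open(out, encoding="utf-8") as fh:
        return json.load(fh)
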