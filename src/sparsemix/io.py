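"""Trace and report serialization.

Traces go to an HDF5 container (one dataset per parameter, sweep-major)
with a JSON sidecar of the prior and sampler configuration; scalar traces
(e0, K0) and the final partition export to CSV.  All files carry a schema
string so future layout changes stay detectable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .model import PriorConfig
from .sampler import McmcOptions, Trace

SCHEMA = "sparsemix-trace-1"

__all__ = ["save_trace", "load_trace", "save_partition_csv", "save_json"]


def _prior_to_dict(prior: PriorConfig) -> dict:
    return {
        "K": prior.K,
        "mean_prior": prior.mean_prior,
        "e0_fixed": prior.e0_fixed,
        "e0_a": prior.e0_a,
        "nu1": prior.nu1,
        "nu2": prior.nu2,
        "m0": prior.m0.tolist(),
        "M0_inv": prior.M0_inv.tolist(),
        "b0_fixed": prior.b0_fixed.tolist(),
        "R0_diag": prior.R0_diag.tolist(),
        "c0": prior.c0,
        "g0": prior.g0,
        "G0": prior.G0.tolist(),
    }


def _options_to_dict(opts: McmcOptions) -> dict:
    return {
        "M": opts.M,
        "burnin": opts.burnin,
        "seed": opts.seed,
        "mh_log_step": opts.mh_log_step,
        "store_allocations": opts.store_allocations,
        "permute": opts.permute,
    }


def save_trace(trace: Trace, path: str) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["acceptance_rate_e0"] = trace.acceptance_rate_e0
        g = f.create_group("draws")
        g.create_dataset("mu", data=trace.mu)
        g.create_dataset("Sigma", data=trace.Sigma)
        g.create_dataset("eta", data=trace.eta)
        g.create_dataset("lam", data=trace.lam)
        g.create_dataset("e0", data=trace.e0)
        g.create_dataset("Nk", data=trace.Nk)
        g.create_dataset("K0", data=trace.K0)
        if trace.S is not None:
            g.create_dataset("S", data=trace.S)
    sidecar = path.with_suffix(path.suffix + ".json")
    save_json(
        {
            "schema": SCHEMA,
            "prior": _prior_to_dict(trace.prior),
            "options": _options_to_dict(trace.options),
        },
        sidecar,
    )


def load_trace(path: str) -> Trace:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    if meta.get("schema") != SCHEMA:
        raise ValueError(f"unknown trace schema {meta.get('schema')!r}")
    p = meta["prior"]
    prior = PriorConfig(
        K=p["K"],
        mean_prior=p["mean_prior"],
        e0_fixed=p["e0_fixed"],
        e0_a=p["e0_a"],
        nu1=p["nu1"],
        nu2=p["nu2"],
        m0=np.asarray(p["m0"]),
        M0_inv=np.asarray(p["M0_inv"]),
        b0_fixed=np.asarray(p["b0_fixed"]),
        R0_diag=np.asarray(p["R0_diag"]),
        c0=p["c0"],
        g0=p["g0"],
        G0=np.asarray(p["G0"]),
    )
    o = meta["options"]
    opts = McmcOptions(**o)
    with h5py.File(path, "r") as f:
        g = f["draws"]
        return Trace(
            mu=g["mu"][()],
            Sigma=g["Sigma"][()],
            eta=g["eta"][()],
            lam=g["lam"][()],
            e0=g["e0"][()],
            Nk=g["Nk"][()],
            K0=g["K0"][()],
            S=g["S"][()] if "S" in g else None,
            acceptance_rate_e0=float(f.attrs["acceptance_rate_e0"]),
            prior=prior,
            options=opts,
        )


def save_partition_csv(
    partition: np.ndarray,
    freq: Optional[np.ndarray],
    path: str,
) -> None:
    """Partition as CSV (1-based labels, max assignment frequency)."""
    df = pd.DataFrame(
        {
            "observation": np.arange(1, partition.shape[0] + 1),
            "label": partition + 1,
        }
    )
    if freq is not None:
        df["max_frequency"] = freq.max(axis=1)
    df.to_csv(path, index=False)


def save_json(obj: dict, path: str) -> None:
    def _default(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        raise TypeError(f"not JSON serializable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
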