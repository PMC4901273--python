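"""Degradation / algorithm sweep engine.

Runs a grid of (degradation kind, level, algorithm) cells, each repeated with
distinct noise seeds on a fixed phantom, and reports per-cell mean and
standard deviation of the relative error — the desk-scale counterpart of the
robustness curves in published FPM comparisons (which average 20 repeats per
condition).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .degrade import DegradationSpec
from .fixtures import make_fixture
from .metrics import relative_error
from .recon import ALGORITHMS, TruncationParams

DEFAULT_REPEATS = 20


def run_cell(
    kind: str,
    level: float,
    algo: str,
    noise_seed: int,
    phantom_seed: int = 0,
    iters: int | None = None,
    a_h: float = 25.0,
    optics=None,
    geometry=None,
) -> float:
    """One reconstruction under one degradation realization; returns RE."""
    fixture = make_fixture(
        seed=phantom_seed,
        degradation=DegradationSpec(kind=kind, level=level, seed=noise_seed),
        optics=optics,
        geometry=geometry,
    )
    runner, default_iters = ALGORITHMS[algo]
    n_iters = default_iters if iters is None else iters
    if algo == "tpwfp":
        result = runner(
            fixture.stack,
            fixture.optics,
            params=TruncationParams(a_h=a_h),
            iters=n_iters,
        )
    else:
        result = runner(fixture.stack, fixture.optics, iters=n_iters)
    return relative_error(result.spectrum, fixture.truth_spectrum)


def run_sweep(
    spec: dict,
    base_seed: int = 0,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run a sweep described by a plain dict (mirrors the YAML sweep file).

    Keys: ``kind`` (degradation), ``levels`` (list), ``algorithms`` (list of
    names), ``repeats`` (default 20), optional ``iters`` per-algorithm
    override dict, optional ``a_h``, optional ``phantom_seed``.

    Per-cell failures are recorded (``error`` column) and the sweep continues.
    """
    kind = spec["kind"]
    levels = list(spec["levels"])
    algorithms = list(spec["algorithms"])
    repeats = int(spec.get("repeats", DEFAULT_REPEATS))
    iters_map = spec.get("iters", {}) or {}
    a_h = float(spec.get("a_h", 25.0))
    phantom_seed = int(spec.get("phantom_seed", base_seed))

    root = np.random.SeedSequence(base_seed)
    children = iter(root.spawn(len(levels) * len(algorithms) * repeats))

    rows = []
    for level in levels:
        for algo in algorithms:
            res, err = [], None
            for _ in range(repeats):
                noise_seed = int(next(children).generate_state(1)[0] % (2**31))
                try:
                    res.append(
                        run_cell(
                            kind,
                            level,
                            algo,
                            noise_seed,
                            phantom_seed=phantom_seed,
                            iters=iters_map.get(algo),
                            a_h=a_h,
                        )
                    )
                except Exception as exc:  # noqa: BLE001 - record and continue
                    err = f"{type(exc).__name__}: {exc}"
            rows.append(
                {
                    "kind": kind,
                    "level": level,
                    "algorithm": algo,
                    "repeats_ok": len(res),
                    "mean_re": float(np.mean(res)) if res else np.nan,
                    "std_re": float(np.std(res, ddof=1)) if len(res) > 1 else (0.0 if res else np.nan),
                    "error": err,
                }
            )
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table
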