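"""JSON round-trip for model parameter files and fit results.

A model file is ``{"family": ..., "params": {...}}`` with family one of
``coxian``, ``ph_dec``, ``ph_inc``, ``exponential``, ``weibull``, ``crbd``.
Fit-result files carry the same fields plus likelihood and AIC metadata so
that downstream commands (goodness of fit, hazard curves, comparison
tables) can consume them without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

from .fitting import FAMILIES, FitResult

__all__ = ["write_model", "read_model", "write_fit", "read_fit"]


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(
            f"unknown model family {family!r}; expected one of {FAMILIES}"
        )


def write_model(family: str, params: dict, path) -> None:
    _check_family(family)
    Path(path).write_text(
        json.dumps({"family": family, "params": params}, indent=2) + "\n"
    )


def read_model(path) -> tuple[str, dict]:
    obj = json.loads(Path(path).read_text())
    _check_family(obj["family"])
    return obj["family"], obj["params"]


def write_fit(f: FitResult, path) -> None:
    obj = {
        "family": f.family,
        "params": f.params,
        "n_phases": f.n_phases,
        "loglik": f.loglik,
        "n_params": f.n_params,
        "aic": f.aic,
        "log_perm": f.log_perm,
        "at_boundary": f.at_boundary,
        "n_starts": f.n_starts,
        "converged": f.converged,
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_fit(path) -> FitResult:
    obj = json.loads(Path(path).read_text())
    _check_family(obj["family"])
    return FitResult(
        family=obj["family"],
        params=obj["params"],
        loglik=obj["loglik"],
        n_params=obj["n_params"],
        aic=obj["aic"],
        n_phases=obj.get("n_phases"),
        log_perm=obj.get("log_perm", 0.0),
        at_boundary=obj.get("at_boundary", False),
        n_starts=obj.get("n_starts", 0),
        converged=obj.get("converged", True),
    )
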