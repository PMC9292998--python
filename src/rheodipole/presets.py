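"""Mapping experimental configurations to model parameters, plus packaged
literature-derived parameter ranges.

Entries in the shipped table are either point estimates (order-of-magnitude,
represented as a single float), ranges (represented as a ``(lo, hi)`` tuple),
or missing (``None``) — missing values are never imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import DomainError
from .flow import ModelParams
from .planar import NondimParams

__all__ = [
    "ExperimentPreset",
    "nondimensionalize",
    "dimensionalize",
    "kappa_from_thresholds",
    "table1_presets",
    "presets_frame",
    "DEFAULT_R0_FRACTION",
]

#: Default dipole scale as a fraction of body length (order of the tail beat).
DEFAULT_R0_FRACTION = 0.2

Entry = float | tuple[float, float] | None


def _validate_entry(name: str, v: Entry) -> None:
    if v is None or isinstance(v, (int, float)):
        return
    lo, hi = v
    if lo > hi:
        raise DomainError(f"{name} interval has lower > upper: {v}")


@dataclass(frozen=True)
class ExperimentPreset:
    """Nondimensional parameter estimates for one published experiment.

    Each of ``rho, eps, alpha, kappa, beta`` is a point value (float), an
    interval (``(lo, hi)``), or ``None`` when the study does not constrain it.
    """

    label: str
    rho: Entry
    eps: Entry
    alpha: Entry = None
    kappa: Entry = None
    beta: Entry = None
    note: str = ""

    def __post_init__(self):
        for name in ("rho", "eps", "alpha", "kappa", "beta"):
            _validate_entry(name, getattr(self, name))

    @staticmethod
    def _mid(v: Entry) -> float | None:
        if v is None:
            return None
        if isinstance(v, (int, float)):
            return float(v)
        return 0.5 * (v[0] + v[1])

    def representative_params(self) -> NondimParams:
        """A single NondimParams from the preset (interval midpoints).

        Missing kappa defaults to 0; missing rho or alpha is an error.
        """
        rho = self._mid(self.rho)
        alpha = self._mid(self.alpha)
        kappa = self._mid(self.kappa)
        if rho is None or alpha is None:
            raise DomainError(
                f"preset {self.label!r} does not constrain "
                f"{'rho' if rho is None else 'alpha'}; cannot build parameters"
            )
        return NondimParams(rho=rho, alpha=alpha, kappa=0.0 if kappa is None else kappa)

    def beta_interval_recomputed(self) -> tuple[float, float] | None:
        """Recompute the beta range from the row's rho, alpha, kappa entries.

        beta = alpha (1 + kappa) / rho^2 is monotone in each argument, so the
        extreme values over the boxes give the interval.  Returns None when
        alpha is missing.
        """
        if self.alpha is None or self.rho is None:
            return None

        def box(v: Entry, default: float | None = None):
            if v is None:
                return (default, default)
            if isinstance(v, (int, float)):
                return (float(v), float(v))
            return (float(v[0]), float(v[1]))

        a_lo, a_hi = box(self.alpha)
        k_lo, k_hi = box(self.kappa, 0.0)
        r_lo, r_hi = box(self.rho)
        return (
            a_lo * (1.0 + k_lo) / r_hi**2,
            a_hi * (1.0 + k_hi) / r_lo**2,
        )


def nondimensionalize(
    h: float, U0: float, eps: float, v0: float, r0: float, l: float, K: float = 0.0
) -> NondimParams:
    """Nondimensional triple from dimensional constants.

    rho = r0/h, alpha = U0*eps/v0, kappa = K*r0*l; beta follows.
    """
    params = ModelParams(h=h, U0=U0, eps=eps, v0=v0, r0=r0, l=l, K=K)
    return params.nondim()


def dimensionalize(nd: NondimParams, h: float, v0: float, eps: float, l: float) -> ModelParams:
    """Recover dimensional constants from a nondimensional triple.

    The nondimensional system fixes only (rho, alpha, kappa); the scales
    (h, v0) and the split factors (eps, l) must be supplied.
    """
    if eps <= 0:
        raise DomainError(f"eps must be positive to recover U0 = alpha*v0/eps, got {eps}")
    r0 = nd.rho * h
    return ModelParams(
        h=h,
        U0=nd.alpha * v0 / eps,
        eps=eps,
        v0=v0,
        r0=r0,
        l=l,
        K=nd.kappa / (r0 * l),
    )


def kappa_from_thresholds(uc_ablated: float, uc_intact: float) -> float:
    """Feedback gain from critical-speed ratio with/without the lateral line.

    The threshold speeds satisfy ``Uc(ablated)/Uc(intact) = 1 + kappa``, so
    ``kappa = ratio - 1``.  A ratio below 1 is clamped to kappa = 0 with a
    warning (the gain cannot be negative).
    """
    if uc_ablated <= 0 or uc_intact <= 0:
        raise DomainError(
            f"threshold speeds must be positive, got ablated={uc_ablated}, intact={uc_intact}"
        )
    kappa = uc_ablated / uc_intact - 1.0
    if kappa < 0:
        warnings.warn(
            f"threshold ratio {uc_ablated / uc_intact:.4g} < 1 implies negative kappa; "
            "clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return kappa


def _entry_from_json(obj) -> Entry:
    if obj is None:
        return None
    if obj["kind"] == "point":
        return float(obj["value"])
    return (float(obj["lo"]), float(obj["hi"]))


def table1_presets() -> list[ExperimentPreset]:
    """The packaged table of literature-derived parameter estimates (9 rows)."""
    raw = json.loads(
        resources.files("rheodipole").joinpath("data/presets.json").read_text()
    )
    return [
        ExperimentPreset(
            label=row["label"],
            rho=_entry_from_json(row["rho"]),
            eps=_entry_from_json(row["eps"]),
            alpha=_entry_from_json(row["alpha"]),
            kappa=_entry_from_json(row["kappa"]),
            beta=_entry_from_json(row["beta"]),
            note=row.get("note", ""),
        )
        for row in raw["presets"]
    ]


def get_preset(label: str) -> ExperimentPreset:
    """Look up a packaged preset by label."""
    for p in table1_presets():
        if p.label == label:
            return p
    labels = ", ".join(p.label for p in table1_presets())
    raise DomainError(f"unknown preset {label!r}; available: {labels}")


def _entry_str(v: Entry) -> str:
    if v is None:
        return ""
    if isinstance(v, (int, float)):
        return f"{v:g}"
    return f"[{v[0]:g}, {v[1]:g}]"


def presets_frame() -> pd.DataFrame:
    """The packaged presets as a DataFrame (for CSV export)."""
    rows = [
        {
            "label": p.label,
            "rho": _entry_str(p.rho),
            "eps": _entry_str(p.eps),
            "alpha": _entry_str(p.alpha),
            "kappa": _entry_str(p.kappa),
            "beta": _entry_str(p.beta),
            "note": p.note,
        }
        for p in table1_presets()
    ]
    return pd.DataFrame(rows)
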