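"""IRMPD–VUV action-spectrum extraction from ion counts.

Model: during the IR macropulse each ground-state molecule is excited with
rate Φσ, so the surviving (intact) fraction after exposure τ is
exp(−Φστ).  The VUV probe then ionises parents and fragments with equal
total probability, and an unknown — but IR-independent — fraction of
parents dissociates during or after ionisation.  Measuring with the IR on
and off therefore gives

    σ = (1/Φτ) · [ ln(P_off/(P_off+F_off)) − ln(P_on/(P_on+F_on)) ]

where P are parent-ion counts and F summed fragment counts; the off-term
cancels the post-ionisation fragmentation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InfiniteDepletionError, ValidationError
from .structures import IonCountRecord, Spectrum


def cross_section_point(r: IonCountRecord) -> float:
    """IR cross-section (units 1/[Φτ]) from one on/off count record.

    Negative values are allowed (noise below the baseline); they are
    flagged downstream, not clamped, so noise statistics stay unbiased.
    """
    if r.p_on == 0:
        raise InfiniteDepletionError(
            f"no surviving parents at {r.nu} cm⁻¹ (infinite depletion)"
        )
    if r.p_off == 0:
        raise InfiniteDepletionError(
            f"no parents in the IR-off reference at {r.nu} cm⁻¹"
        )
    off = np.log(r.p_off / (r.p_off + r.f_off))
    on = np.log(r.p_on / (r.p_on + r.f_on))
    return float((off - on) / r.phi_tau)


def cross_section_stderr(r: IonCountRecord) -> float:
    """Binomial standard error of :func:`cross_section_point`.

    Treats P/(P+F) in each shutter state as a binomial proportion:
    var[ln p̂] ≈ (1−p̂)/(n·p̂).
    """
    var = 0.0
    for p, f in ((r.p_on, r.f_on), (r.p_off, r.f_off)):
        n = p + f
        phat = p / n
        var += (1.0 - phat) / (n * phat)
    return float(np.sqrt(var) / r.phi_tau)


def fluence(pulse_energy_mj: float, nu: float, constant: float = 1.0) -> float:
    """Macropulse photon measure Φτ ∝ pulse energy / photon energy.

    Photon count scales as E/(hcν); the proportionality constant is
    configurable and defaults to 1 (Φτ is only ever needed up to a
    common factor).
    """
    if pulse_energy_mj < 0:
        raise ValidationError("pulse energy must be non-negative")
    if nu <= 0:
        raise ValidationError("frequency must be positive")
    return constant * pulse_energy_mj / nu


def build_action_spectrum(
    records: Sequence[IonCountRecord],
    grid: np.ndarray | None = None,
) -> pd.DataFrame | Spectrum:
    """Per-frequency cross-sections from a set of count records.

    Returns a DataFrame with columns ``nu``, ``sigma``, ``stderr`` and
    ``negative`` (noise-below-baseline flag), sorted by frequency;
    duplicate frequencies are averaged with a warning.  If ``grid`` is
    given, the curve is linearly interpolated onto it and returned as a
    uniform :class:`Spectrum`.
    """
    if not records:
        raise ValidationError("no ion-count records")
    rows = [(r.nu, cross_section_point(r), cross_section_stderr(r))
            for r in records]
    df = pd.DataFrame(rows, columns=["nu", "sigma", "stderr"])
    if df["nu"].duplicated().any():
        warnings.warn("duplicate frequencies averaged")
        df = df.groupby("nu", as_index=False).mean()
    df = df.sort_values("nu", ignore_index=True)
    df["negative"] = df["sigma"] < 0
    if grid is not None:
        values = np.interp(grid, df["nu"], df["sigma"])
        return Spectrum(np.asarray(grid, float), values,
                        provenance="irmpd-action")
    return df
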