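"""Haar wavelet compression and conformational selection (OWSCA).

A distance trajectory of a few thousand MD frames is highly redundant:
consecutive frames are strongly correlated and most of the fluctuation
energy lives in a small number of wavelet coefficients.  The selection
scheme implemented here compresses the distance signal with the
orthonormal Haar (db1) discrete wavelet transform, keeps the smallest
set of largest-magnitude detail coefficients that captures a prescribed
fraction of the fluctuation energy, and maps each retained coefficient
to the frame at the midpoint of its dyadic support.  Those frames are
the representative conformations carried into the relaxation analysis.

Only the Haar wavelet is supported: its piecewise-constant,
discontinuous profile suits distance signals with abrupt transitions,
and dyadic supports give an unambiguous coefficient-to-frame mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pywt

from .trajectory import DistanceTrajectory

__all__ = [
    "WaveletDecomposition",
    "SelectionPolicy",
    "SelectionResult",
    "haar_dwt",
    "inverse_haar",
    "select_conformations",
    "DEFAULT_POLICY",
]

_WAVELET = "db1"
_MODE = "periodization"  # exact orthonormal transform on power-of-two input


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


@dataclass(frozen=True)
class WaveletDecomposition:
    """Orthonormal Haar analysis of a (padded) signal.

    ``details[j]`` holds the level-j detail coefficients d_{j,k}; j runs
    from 1 (finest, support of 2 samples) to ``levels`` (coarsest).
    ``approximation`` holds the coarsest scaling coefficients.  The
    signal is edge-padded to ``padded_length`` (the smallest power of
    two >= ``original_length``) before analysis, which avoids the
    spurious boundary detail coefficients zero-padding would create.
    """

    wavelet_name: str
    levels: int
    details: dict
    approximation: np.ndarray
    original_length: int
    padded_length: int
    padding_mode: str = "edge"

    def coefficient_items(self):
        """Yield ((j, k), value) over all detail coefficients."""
        for j in range(1, self.levels + 1):
            for k, v in enumerate(self.details[j]):
                yield (j, k), float(v)

    @property
    def total_energy(self) -> float:
        """Sum of squared coefficients = padded-signal energy (Parseval)."""
        e = float(np.sum(self.approximation**2))
        for j in range(1, self.levels + 1):
            e += float(np.sum(self.details[j] ** 2))
        return e

    @property
    def detail_energy(self) -> float:
        """Fluctuation energy: squared detail coefficients only."""
        return self.total_energy - float(np.sum(self.approximation**2))

    def support_midpoint(self, j: int, k: int) -> int:
        """Sample index at the centre of coefficient (j, k)'s support.

        A level-j coefficient summarizes samples [k 2^j, (k+1) 2^j);
        indices falling in the padded tail clamp to the last real frame.
        """
        mid = k * (1 << j) + (1 << (j - 1))
        return min(mid, self.original_length - 1)

    def approximation_midpoints(self) -> list[int]:
        span = 1 << self.levels
        mids = [
            min(k * span + span // 2, self.original_length - 1)
            for k in range(self.approximation.size)
        ]
        return sorted(set(mids))


def haar_dwt(signal, max_level: int | None = None) -> WaveletDecomposition:
    """Full orthonormal Haar decomposition of ``signal``.

    The signal is edge-padded to the next power of two; ``max_level``
    defaults to the full depth log2(padded_length).
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"signal must have length >= 2, got {x.size}")
    padded_length = _next_pow2(x.size)
    full_depth = int(np.log2(padded_length))
    if max_level is None:
        max_level = full_depth
    if not 1 <= max_level <= full_depth:
        raise ValueError(
            f"max_level must be in [1, {full_depth}], got {max_level}"
        )
    padded = np.pad(x, (0, padded_length - x.size), mode="edge")
    coeffs = pywt.wavedec(padded, _WAVELET, mode=_MODE, level=max_level)
    approximation = coeffs[0]
    # pywt orders [cA_L, cD_L, ..., cD_1]; re-key so details[1] is finest.
    details = {
        max_level - i: np.asarray(c) for i, c in enumerate(coeffs[1:])
    }
    return WaveletDecomposition(
        wavelet_name=_WAVELET,
        levels=max_level,
        details=details,
        approximation=np.asarray(approximation),
        original_length=x.size,
        padded_length=padded_length,
    )


def inverse_haar(dec: WaveletDecomposition, truncate: bool = True) -> np.ndarray:
    """Synthesis: reconstruct the signal from a decomposition.

    Returns the original-length signal (padding removed) unless
    ``truncate`` is False, in which case the padded signal is returned.
    """
    if sorted(dec.details) != list(range(1, dec.levels + 1)):
        raise ValueError("decomposition is missing detail levels")
    coeffs = [dec.approximation] + [
        dec.details[j] for j in range(dec.levels, 0, -1)
    ]
    x = pywt.waverec(coeffs, _WAVELET, mode=_MODE)
    return x[: dec.original_length] if truncate else x


@dataclass(frozen=True)
class SelectionPolicy:
    """Retention policy for the wavelet selection.

    ``energy_fraction`` is the fraction of the fluctuation (detail)
    energy that the retained detail coefficients must capture; the
    approximation coefficients are always retained.  The retained-frame
    count is clamped to [min_keep, max_keep] when bounds are given.
    """

    energy_fraction: float = 0.65
    min_keep: int = 2
    max_keep: int | None = None
    max_level: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.energy_fraction <= 1.0:
            raise ValueError(
                f"energy_fraction must be in (0, 1], got {self.energy_fraction}"
            )
        if self.min_keep < 2:
            raise ValueError(f"min_keep must be >= 2, got {self.min_keep}")
        if self.max_keep is not None and self.max_keep < self.min_keep:
            raise ValueError("max_keep must be >= min_keep")


DEFAULT_POLICY = SelectionPolicy()


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the wavelet conformational selection."""

    selected_frame_ids: np.ndarray
    retained_coefficient_keys: list
    energy_fraction_captured: float
    compressed_signal: np.ndarray
    policy: SelectionPolicy = field(default=DEFAULT_POLICY)

    @property
    def n_selected(self) -> int:
        return int(self.selected_frame_ids.size)

    def to_json_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "energy_fraction_captured": self.energy_fraction_captured,
            "n_retained_coefficients": len(self.retained_coefficient_keys),
            "policy": {
                "energy_fraction": self.policy.energy_fraction,
                "min_keep": self.policy.min_keep,
                "max_keep": self.policy.max_keep,
                "max_level": self.policy.max_level,
            },
        }


def select_conformations(
    traj: DistanceTrajectory, policy: SelectionPolicy = DEFAULT_POLICY
) -> SelectionResult:
    """Pick representative frames by Haar-coefficient energy ranking.

    Detail coefficients are ranked globally by squared magnitude and the
    smallest prefix whose cumulative energy reaches
    ``policy.energy_fraction`` of the total detail energy is retained
    (plus all approximation coefficients).  Each retained coefficient
    maps to the frame at its dyadic-support midpoint; midpoints are
    deduplicated and sorted.  Deterministic for a given signal and
    policy; ties in coefficient magnitude break toward finer levels and
    earlier positions.
    """
    dec = haar_dwt(traj.distances, max_level=policy.max_level)
    keys, values = [], []
    for key, v in dec.coefficient_items():
        keys.append(key)
        values.append(v)
    values = np.asarray(values)
    energies = values**2
    total_detail = float(energies.sum())

    order = np.argsort(-energies, kind="stable")
    if total_detail == 0.0:  # constant signal: approximation carries all
        n_retained = 0
        captured = 1.0
    else:
        cum = np.cumsum(energies[order]) / total_detail

        n_retained = int(np.searchsorted(cum, policy.energy_fraction) + 1)
        n_retained = min(n_retained, order.size)
        captured = float(cum[n_retained - 1])

    retained_idx = list(order[:n_retained])
    retained_keys = [keys[i] for i in retained_idx]

    def frame_set(detail_keys) -> np.ndarray:
        mids = set(dec.approximation_midpoints())
        mids.update(dec.support_midpoint(j, k) for j, k in detail_keys)
        return np.array(sorted(mids), dtype=int)

    frames = frame_set(retained_keys)
    # Clamp the frame count by adding next-ranked / dropping
    # smallest-magnitude detail mappings.
    while frames.size < policy.min_keep and n_retained < order.size:
        n_retained += 1
        retained_keys = [keys[i] for i in order[:n_retained]]
        frames = frame_set(retained_keys)
    if policy.max_keep is not None:
        while frames.size > policy.max_keep and n_retained > 0:
            n_retained -= 1
            retained_keys = [keys[i] for i in order[:n_retained]]
            frames = frame_set(retained_keys)
    if total_detail > 0 and n_retained > 0:
        captured = float(
            energies[order[:n_retained]].sum() / total_detail
        )
    elif total_detail > 0:
        captured = 0.0

    # Compressed signal: zero every non-retained detail coefficient.
    kept = set(retained_keys)
    sparse_details = {}
    for j in range(1, dec.levels + 1):
        d = np.zeros_like(dec.details[j])
        for k in range(d.size):
            if (j, k) in kept:
                d[k] = dec.details[j][k]
        sparse_details[j] = d
    sparse = WaveletDecomposition(
        wavelet_name=dec.wavelet_name,
        levels=dec.levels,
        details=sparse_details,
        approximation=dec.approximation,
        original_length=dec.original_length,
        padded_length=dec.padded_length,
        padding_mode=dec.padding_mode,
    )
    compressed = inverse_haar(sparse)

    return SelectionResult(
        selected_frame_ids=frames,
        retained_coefficient_keys=retained_keys,
        energy_fraction_captured=captured,
        compressed_signal=compressed,
        policy=policy,
    )


def write_selection(result: SelectionResult, index_path, json_path) -> None:
    """Frame indices as a one-column text file plus a JSON sidecar."""
    np.savetxt(index_path, result.selected_frame_ids, fmt="%d")
    with open(json_path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2)
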