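"""Exact integer arithmetic on the hexagonal capsid lattice.

A Caspar-Klug icosahedral capsid is classified by its triangulation
number ``T(h, k) = h^2 + h*k + k^2``, where ``(h, k)`` are the integer
steps on the hexagonal lattice joining two nearby pentamers.  This
module provides the T-number Diophantine arithmetic: evaluation,
canonicalization under the hexagonal point group, enumeration of all
T-numbers up to a bound, the centered-hexamer criterion (a hexamer sits
on a global 3-fold axis if and only if ``3 | T``), and the sublattice
transformation linking a T-number divisible by three to the steps
``(h_H, k_H)`` that reach the hexamer on the face centroid, with
``T = 3 * T(h_H, k_H)``.

Everything here is exact integer arithmetic; the 3-D geometric
counterpart (and the brute-force oracle for the centered-hexamer
criterion) lives in :mod:`capsidlattice.symmetry_census`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InvalidStepError, NoCenteredHexamerError, NotATNumberError

__all__ = [
    "AxialStep",
    "CentroidSteps",
    "TNumberRecord",
    "t_number",
    "canonicalize",
    "point_group_images",
    "is_t_number",
    "enumerate_t_numbers",
    "predict_centered_hexamer",
    "centroid_steps",
    "expand_by_three",
]


class AxialStep(NamedTuple):
    """Integer steps ``(h, k)`` along the two hexagonal basis directions
    (60 degrees apart) joining two nearby pentamers."""

    h: int
    k: int


class CentroidSteps(NamedTuple):
    """Steps ``(h_H, k_H)`` joining a pentamer with the hexamer sitting
    on the face centroid (a global 3-fold axis).  Defined only when the
    parent T-number is divisible by three."""

    hH: int
    kH: int


@dataclass(frozen=True)
class TNumberRecord:
    """One triangulation number with all its canonical step
    representations and the centered-hexamer prediction ``3 | T``."""

    T: int
    representations: tuple[AxialStep, ...]
    centered_hexamer_predicted: bool

    @property
    def has_hexamers(self) -> bool:
        return self.T > 1


def _check_step(step) -> AxialStep:
    h, k = step
    if not (isinstance(h, int) and isinstance(k, int)):
        raise InvalidStepError(f"lattice steps must be integers, got {step!r}")
    if h == 0 and k == 0:
        raise InvalidStepError("the zero step (0, 0) does not define a capsid")
    return AxialStep(h, k)


def t_number(step) -> int:
    """Triangulation number ``T = h^2 + h*k + k^2`` of a lattice step.

    Invariant under the 12 hexagonal point-group images of the step.
    """
    h, k = _check_step(step)
    return h * h + h * k + k * k


def point_group_images(step) -> list[AxialStep]:
    """All 12 images of a step under the hexagonal point group
    (6 rotations by 60 degrees, each optionally composed with the
    ``(h, k) -> (k, h)`` mirror).  May contain duplicates for steps on
    mirror lines."""
    h, k = _check_step(step)
    images = []
    for a, b in ((h, k), (k, h)):
        for _ in range(6):
            images.append(AxialStep(a, b))
            a, b = -b, a + b  # rotation by 60 degrees
    return images


def canonicalize(step) -> AxialStep:
    """Canonical representative ``h >= k >= 0`` of a step's point-group
    orbit.  Preserves the T-number."""
    candidates = {s for s in point_group_images(step) if s.h >= s.k >= 0}
    if len(candidates) != 1:  # pragma: no cover - sector is a fundamental domain
        raise InvalidStepError(f"no unique canonical image for {step!r}: {candidates}")
    return candidates.pop()


def is_t_number(T: int) -> bool:
    """Whether ``T`` is achievable as ``h^2 + h*k + k^2`` (exhaustive
    search over ``0 <= k <= h <= ceil(sqrt(T))``)."""
    if not isinstance(T, int) or T < 1:
        return False
    bound = math.isqrt(T) + 1
    for h in range(1, bound + 1):
        for k in range(0, h + 1):
            if h * h + h * k + k * k == T:
                return True
    return False


def enumerate_t_numbers(t_max: int) -> list[TNumberRecord]:
    """All distinct triangulation numbers ``T <= t_max``, each with its
    full set of canonical representations, sorted by T.

    A T-number with several inequivalent representations (the smallest
    is T=49, reached by both (7,0) and (5,3)) yields a single record
    listing all of them.
    """
    if not isinstance(t_max, int) or t_max < 1:
        raise InvalidStepError(f"t_max must be a positive integer, got {t_max!r}")
    reps: dict[int, set[AxialStep]] = {}
    bound = math.isqrt(t_max) + 1
    for h in range(1, bound + 1):
        for k in range(0, h + 1):
            T = h * h + h * k + k * k
            if T <= t_max:
                reps.setdefault(T, set()).add(AxialStep(h, k))
    return [
        TNumberRecord(
            T=T,
            representations=tuple(sorted(steps)),
            centered_hexamer_predicted=(T % 3 == 0),
        )
        for T, steps in sorted(reps.items())
    ]


def predict_centered_hexamer(T: int) -> bool:
    """Lattice-arithmetic prediction of the centered-hexamer criterion:
    the capsid contains a hexamer centered on a global 3-fold axis if
    and only if ``T`` is a multiple of three.

    Raises :class:`NotATNumberError` for integers (2, 5, 6, ...) that no
    step ``(h, k)`` can reach.
    """
    if not is_t_number(T):
        raise NotATNumberError(f"{T!r} is not a triangulation number")
    return T % 3 == 0


def centroid_steps(step) -> CentroidSteps:
    """Steps from a pentamer to the face-centroid hexamer.

    For a canonical step with ``3 | T`` the face centroid of the
    triangle spanned by ``(h, k)`` and its 60-degree rotation
    ``(-k, h+k)`` is itself a lattice point, at
    ``((h - k) / 3, (h + 2k) / 3)``; these are the steps to the hexamer
    sitting on the global 3-fold axis, and they satisfy
    ``3 * T(h_H, k_H) = T(h, k)``.
    """
    h, k = canonicalize(step)
    T = h * h + h * k + k * k
    if T % 3 != 0:
        raise NoCenteredHexamerError(
            f"T({h},{k}) = {T} is not divisible by 3: no hexamer sits on a "
            "global 3-fold axis"
        )
    # 3 | T  <=>  h ≡ k (mod 3), so the divisions below are exact.
    hH, kH = (h - k) // 3, (h + 2 * k) // 3
    assert 3 * (hH * hH + hH * kH + kH * kH) == T
    return CentroidSteps(hH, kH)


def expand_by_three(step) -> AxialStep:
    """The canonical step whose T-number is three times that of ``step``.

    Implemented as ``(h, k) -> (2h + k, k - h)`` followed by
    canonicalization; algebraically
    ``T(2h+k, k-h) = 3(h^2 + hk + k^2)`` identically.  Round-trips with
    :func:`centroid_steps`: every T-number times three is again a
    T-number, and the product is divisible by three, so the expanded
    capsid always has a hexamer centered on each global 3-fold axis.
    """
    h, k = _check_step(step)
    return canonicalize(AxialStep(2 * h + k, k - h))
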