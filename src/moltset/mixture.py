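"""Staging-contamination mixture model.

A pooled population nominally in one developmental state that contains a
fraction ``f`` of molting (lethargus) animals yields, for a gene whose
lethargus:non-lethargus linear expression ratio is ``R``, an apparent fold
change of ``(1 - f) + f * R`` relative to a pure population. The mixing is
linear in molecules: pooling RNA is additive on intensity scale, not on
logs. A 0.5% lethargus contamination of a gene expressed 200-fold higher
during the molt therefore looks like a ~2-fold induction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MixtureScenario", "apparent_fold", "required_fraction"]


def apparent_fold(f: float, ratio: float) -> float:
    """Apparent linear fold change of a mixed population vs a pure one.

    Parameters
    ----------
    f
        Contamination fraction in [0, 1].
    ratio
        Lethargus : non-lethargus linear expression ratio (>= 0).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"contamination fraction must lie in [0, 1], got {f}")
    if ratio < 0:
        raise ValueError(f"expression ratio must be >= 0, got {ratio}")
    return (1.0 - f) + f * ratio


def required_fraction(target_fold: float, ratio: float) -> float:
    """Contamination fraction producing a given apparent fold change.

    Inverse of :func:`apparent_fold`: ``f = (target - 1) / (ratio - 1)``.
    The target must lie between 1 and ``ratio`` (in either order); a ratio
    of exactly 1 cannot change the apparent fold.
    """
    if ratio == 1.0:
        raise ValueError("ratio 1 cannot produce any apparent fold change")
    if ratio < 0:
        raise ValueError(f"expression ratio must be >= 0, got {ratio}")
    f = (target_fold - 1.0) / (ratio - 1.0)
    if not 0.0 <= f <= 1.0:
        raise ValueError(
            f"target fold {target_fold} is not reachable with ratio {ratio} "
            "(must lie between 1 and the ratio)"
        )
    return f


@dataclass(frozen=True)
class MixtureScenario:
    """A contamination fraction and expression ratio with the derived fold."""

    f: float
    ratio: float

    def __post_init__(self) -> None:
        apparent_fold(self.f, self.ratio)  # validates

    @property
    def apparent_fold(self) -> float:
        return apparent_fold(self.f, self.ratio)
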