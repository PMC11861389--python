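"""Cost-function weights and iteration controls for the tracker.

The regularized cost combines, per pixel, a squared data-fidelity residual,
adaptive first-order L1 continuity (weights ``wf * {alpha1s, alpha2s,
beta1s, beta2s}``), unmixed second-order L1 continuity (``ws * {alpha1s,
alpha2s, beta1s, beta2s}``), mixed second-order L1 continuity
(``ws * {alpha_mix, beta_mix}``) and an effective-Poisson's-ratio
mechanical-consistency term (``alpha3s``). The presets below are
cross-validated values for three acquisition classes; the beta weights
follow fixed ratios of the alphas (beta1s = 2 alpha1s / 3,
beta2s = alpha2s / 4, beta_mix = alpha_mix / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .exceptions import ConfigError, ParameterError

__all__ = ["TrackingParams", "PRESETS", "preset"]


@dataclass(frozen=True)
class TrackingParams:
    """All tunable weights and iteration controls of the tracker.

    Attributes
    ----------
    wf, ws
        Global strengths of first- and second-order continuity.
    alpha1s, alpha2s
        Axial-displacement continuity weights (axial / lateral derivative).
    beta1s, beta2s
        Lateral-displacement continuity weights (axial / lateral derivative).
    alpha_mix, beta_mix
        Mixed second-derivative weights for the axial / lateral field;
        setting both to zero recovers the unmixed-only baseline.
    alpha3s
        Mechanical-consistency (effective Poisson's ratio) weight.
    l1_delta
        Smoothing constant of the differentiable |x| ~ sqrt(x^2 + delta^2),
        in strain-like (sample-per-sample) units.
    n_outer_iters, conv_tol
        Outer-iteration count and sup-norm increment tolerance (samples).
    nu_nominal, nu_bounds
        Initial effective Poisson's ratio and its clamping interval.
    eps_window
        Odd moving-average window (samples) for the adaptive first-order
        offsets derived from the initial displacement field.
    """

    wf: float = 0.001
    ws: float = 0.025
    alpha1s: float = 150.0
    alpha2s: float = 0.2
    alpha3s: float = 0.045
    alpha_mix: float = 56.25
    beta1s: float = 100.0
    beta2s: float = 0.05
    beta_mix: float = 28.125
    l1_delta: float = 1e-4
    n_outer_iters: int = 10
    conv_tol: float = 1e-3
    nu_nominal: float = 0.49
    nu_bounds: tuple[float, float] = (0.0, 0.5)
    eps_window: int = 21

    def __post_init__(self) -> None:
        nonneg = (
            "wf", "ws", "alpha1s", "alpha2s", "alpha3s", "alpha_mix",
            "beta1s", "beta2s", "beta_mix",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.l1_delta > 0:
            raise ParameterError("l1_delta must be > 0")
        if self.n_outer_iters < 1:
            raise ParameterError("n_outer_iters must be >= 1")
        if not self.conv_tol > 0:
            raise ParameterError("conv_tol must be > 0")
        lo, hi = self.nu_bounds
        if not (0.0 <= lo < hi <= 0.5):
            raise ParameterError(f"nu_bounds must satisfy 0 <= lo < hi <= 0.5, got {self.nu_bounds}")
        if not lo <= self.nu_nominal < 0.5:
            raise ParameterError(
                f"nu_nominal {self.nu_nominal} outside [{lo}, 0.5)"
            )
        if self.eps_window < 3 or self.eps_window % 2 == 0:
            raise ParameterError("eps_window must be odd and >= 3")

    @classmethod
    def from_alphas(
        cls,
        alpha1s: float,
        alpha2s: float,
        alpha3s: float,
        alpha_mix: float,
        wf: float,
        ws: float,
        **kwargs,
    ) -> "TrackingParams":
        """Build params with the betas at their standard ratios."""
        return cls(
            wf=wf,
            ws=ws,
            alpha1s=alpha1s,
            alpha2s=alpha2s,
            alpha3s=alpha3s,
            alpha_mix=alpha_mix,
            beta1s=2.0 * alpha1s / 3.0,
            beta2s=alpha2s / 4.0,
            beta_mix=alpha_mix / 2.0,
            **kwargs,
        )

    def without_mixed(self) -> "TrackingParams":
        """The unmixed-only baseline: mixed weights zeroed, rest unchanged."""
        return replace(self, alpha_mix=0.0, beta_mix=0.0)

    def replace(self, **kwargs) -> "TrackingParams":
        return replace(self, **kwargs)


def _make_presets() -> dict[str, TrackingParams]:
    return {
        "simulated": TrackingParams.from_alphas(
            alpha1s=150.0, alpha2s=0.2, alpha3s=0.045, alpha_mix=56.25,
            wf=0.001, ws=0.025,
        ),
        "phantom": TrackingParams.from_alphas(
            alpha1s=120.0, alpha2s=0.4, alpha3s=0.036, alpha_mix=45.0,
            wf=0.0006, ws=0.01,
        ),
        "in_vivo": TrackingParams.from_alphas(
            alpha1s=20.0, alpha2s=0.05, alpha3s=0.006, alpha_mix=7.5,
            wf=0.0006, ws=0.01,
        ),
    }


#: Cross-validated parameter presets per acquisition class.
PRESETS: dict[str, TrackingParams] = _make_presets()


def preset(name: str, **overrides) -> TrackingParams:
    """Look up a named preset, optionally overriding individual fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return base.replace(**overrides) if overrides else base
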