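"""Parameter sets for the neural mass and hemodynamic forward models.

Both parameter containers are plain frozen-by-convention dataclasses with an
explicit :meth:`validate` so that invalid values fail loudly at construction
time rather than deep inside a numba kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace


@dataclass
class DmfParameters:
    """Constants of the excitatory-inhibitory dynamic mean-field model.

    The defaults are the standard biophysically calibrated values of the
    reduced Wong-Wang model with NMDA-mediated excitation and GABA-A
    mediated inhibition.  Units follow the usual convention of the model:
    currents in nA, rates in Hz, time constants in ms.

    Attributes
    ----------
    a_E, b_E, d_E : float
        Gain (nA^-1), threshold (Hz) and shape (s) of the excitatory
        input-output transfer function.
    a_I, b_I, d_I : float
        Same for the inhibitory population.
    gamma_kinetic : float
        Kinetic rate of NMDA gating, 0.641/1000 per ms (the factor 1000
        expresses rate constants in ms).
    tau_E, tau_I : float
        NMDA and GABA synaptic time constants, ms.
    I0 : float
        Overall effective external input, nA.
    W_E, W_I : float
        External-input scaling for the excitatory / inhibitory pool.
    w_plus : float
        Local excitatory recurrence.
    J_NMDA : float
        Excitatory synaptic coupling, nA.
    sigma_noise : float
        Amplitude of the additive Gaussian noise on the gating variables, nA.
    G : float
        Global coupling scaling all long-range excitatory connections
        (the model's only free parameter).
    """

    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    gamma_kinetic: float = 0.641 / 1000.0
    tau_E: float = 100.0
    tau_I: float = 10.0
    I0: float = 0.382
    W_E: float = 1.0
    W_I: float = 0.7
    w_plus: float = 1.4
    J_NMDA: float = 0.15
    sigma_noise: float = 0.01
    G: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.gamma_kinetic <= 0:
            raise ValueError("gamma_kinetic must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        if self.G < 0:
            raise ValueError("G must be nonnegative")
        for name in ("a_E", "a_I", "d_E", "d_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kwargs) -> "DmfParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HemodynamicParameters:
    """Constants of the Balloon-Windkessel hemodynamic model.

    ``kappa`` (signal decay), ``gamma_h`` (flow-dependent elimination) and
    ``tau_h`` (hemodynamic transit time) are in s^-1, s^-1 and s; ``alpha``
    is Grubb's vessel stiffness exponent and ``rho_h`` the resting oxygen
    extraction fraction.  ``V0`` and ``k1..k3`` weight the extra- and
    intravascular contributions to the BOLD signal.

    The vasodilatory drive is a linear function ``c1 * rate + c0`` of the
    regional excitatory firing rate.  The default ``(c1, c0) = (0.5, 3.0)``
    follows the rate-modified drive of the whole-brain model; the classical
    convention ``(1, 0)`` on normalised activity is available through
    :meth:`standard`.
    """

    kappa: float = 0.65
    gamma_h: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho_h: float = 0.34
    V0: float = 0.02
    k1: float = field(default=7.0 * 0.34)
    k2: float = 2.0
    k3: float = 2.0 * 0.34 - 0.2
    drive_slope: float = 0.5
    drive_offset: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.tau_h, self.kappa, self.gamma_h) <= 0:
            raise ValueError("tau_h, kappa and gamma_h must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.rho_h < 1:
            raise ValueError("rho_h must lie in (0, 1)")

    @classmethod
    def standard(cls, **kwargs) -> "HemodynamicParameters":
        """Classical drive convention: unit slope, no offset."""
        kwargs.setdefault("drive_slope", 1.0)
        kwargs.setdefault("drive_offset", 0.0)
        return cls(**kwargs)

    def with_(self, **kwargs) -> "HemodynamicParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
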