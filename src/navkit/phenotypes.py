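"""Ground-truth channel phenotypes for the synthetic voltage-clamp generator.

A :class:`ChannelPhenotype` bundles every generative parameter needed to
emit whole-cell Na+ current sweeps for one genotype x temperature
condition: peak current density, activation/availability Boltzmann
parameters, voltage-dependent fast-inactivation onset time constants,
the persistent (non-inactivating) current fraction, and recovery
kinetics.

The packaged defaults for the wild-type (WT) and L1624Q NaV1.1 channel
at 22 degC and 37 degC install the measured headline values of the study
system (current densities at 37 degC, persistent fractions at both
temperatures, and the 1.485-fold acceleration of fast-inactivation
onset in L1624Q at 37 degC).  Quantities the source experiments report
only graphically (V1/2s, slope factors, absolute tau values, recovery
constants) carry documented representative NaV1.1 values; they are
overridable and are not treated as measured anchors anywhere in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ChannelPhenotype", "default_phenotype", "UnsupportedConditionError"]


class UnsupportedConditionError(ValueError):
    """Raised when no packaged phenotype exists for a genotype/temperature."""


# Inactivation-onset acceleration of L1624Q at 37 degC: tau_LQ = tau_WT / 1.485.
INACT_RATE_FACTOR_LQ_37 = 1.485

# tau of fast-inactivation onset (ms) for WT at 22 degC on the reporting
# grid -30..+20 mV.  Representative NaV1.1 values anchored at
# tau(0 mV) = 0.8 ms; monotonically accelerating with depolarization.
_TAU_ONSET_WT_22 = {-30: 2.0, -20: 1.5, -10: 1.1, 0: 0.8, 10: 0.65, 20: 0.55}

# Temperature scaling of onset kinetics: tau(0 mV) = 0.35 ms at 37 degC.
_TAU_SCALE_37 = 0.35 / 0.8


@dataclass(frozen=True)
class ChannelPhenotype:
    """Generative parameters for one genotype x temperature condition.

    Attributes
    ----------
    genotype : str
        "WT", "L1624Q", or a custom label.
    temperature : float
        Recording temperature in degC.
    density_at_0mV : float
        Peak current density magnitude at 0 mV in pA/pF.  Currents are
        emitted inward-negative; this field stores the magnitude.
    v_half_act, k_act : float
        Midpoint (mV) and slope factor (mV, > 0) of the activation
        Boltzmann a_inf(V).
    v_rev : float
        Reversal potential of the Na+ current, mV.
    v_half_inact, k_inact : float
        Midpoint and slope factor of steady-state fast inactivation
        (descending Boltzmann h_inf(V)).
    tau_onset_table : dict
        Voltage (mV) -> fast-inactivation onset time constant (ms).
    f_persistent : float
        Non-inactivating fraction of peak current, in [0, 1).
    rec_tau_fast, rec_tau_slow : float
        Double-exponential recovery time constants at -90 mV, ms.
    rec_frac_fast : float
        Amplitude fraction of the fast recovery component, in [0, 1].
    """

    genotype: str
    temperature: float
    density_at_0mV: float
    v_half_act: float = -22.0
    k_act: float = 7.0
    v_rev: float = 65.0
    v_half_inact: float = -60.0
    k_inact: float = 6.0
    tau_onset_table: dict = field(default_factory=lambda: dict(_TAU_ONSET_WT_22))
    f_persistent: float = 0.01
    rec_tau_fast: float = 2.0
    rec_tau_slow: float = 50.0
    rec_frac_fast: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.f_persistent < 1.0):
            raise ValueError(f"f_persistent must be in [0, 1): {self.f_persistent}")
        if self.k_act <= 0:
            raise ValueError(f"k_act must be > 0: {self.k_act}")
        if self.density_at_0mV < 0:
            raise ValueError(f"density_at_0mV is a magnitude, must be >= 0")
        for v, tau in self.tau_onset_table.items():
            if tau <= 0:
                raise ValueError(f"tau_onset({v} mV) must be > 0: {tau}")
        if not (0.0 <= self.rec_frac_fast <= 1.0):
            raise ValueError(f"rec_frac_fast must be in [0, 1]: {self.rec_frac_fast}")
        if self.rec_tau_fast <= 0 or self.rec_tau_slow <= 0:
            raise ValueError("recovery time constants must be > 0")

    def tau_onset(self, voltage: float) -> float:
        """Onset time constant at `voltage`, with linear interpolation
        between tabulated grid points.  Outside the table the nearest
        endpoint value is used (clamped extrapolation)."""
        table = self.tau_onset_table
        if voltage in table:
            return table[voltage]
        vs = sorted(table)
        if voltage <= vs[0]:
            return table[vs[0]]
        if voltage >= vs[-1]:
            return table[vs[-1]]
        import bisect

        i = bisect.bisect_left(vs, voltage)
        v0, v1 = vs[i - 1], vs[i]
        w = (voltage - v0) / (v1 - v0)
        return (1 - w) * table[v0] + w * table[v1]

    def with_(self, **kwargs) -> "ChannelPhenotype":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        """Plain-type representation (YAML/JSON compatible)."""
        from dataclasses import asdict

        d = asdict(self)
        d["tau_onset_table"] = {float(k): float(v)
                                for k, v in d["tau_onset_table"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelPhenotype":
        d = dict(d)
        d["tau_onset_table"] = {float(k): float(v)
                                for k, v in d["tau_onset_table"].items()}
        return cls(**d)


def _scaled_tau_table(scale: float) -> dict:
    return {v: t * scale for v, t in _TAU_ONSET_WT_22.items()}


# Packaged conditions.  Measured anchors: densities at 37 degC
# (WT 72.82, L1624Q 45.42 pA/pF), persistent fractions at both
# temperatures (WT 0.95%/2.27%, L1624Q 3.20%/4.58%), and the 1.485-fold
# faster inactivation onset of L1624Q at 37 degC.  Densities at 22 degC
# (no genotype difference measured there) and the SSFI midpoint shift
# with temperature (+4 mV, direction measured, magnitude representative)
# are documented defaults.
_CONDITIONS = {
    ("WT", 22): dict(
        density_at_0mV=60.0,
        f_persistent=0.0095,
        tau_onset_table=_scaled_tau_table(1.0),
        v_half_inact=-60.0,
    ),
    ("L1624Q", 22): dict(
        density_at_0mV=60.0,
        f_persistent=0.0320,
        tau_onset_table=_scaled_tau_table(1.0),
        v_half_inact=-60.0,
    ),
    ("WT", 37): dict(
        density_at_0mV=72.82,
        f_persistent=0.0227,
        tau_onset_table=_scaled_tau_table(_TAU_SCALE_37),
        v_half_inact=-56.0,
    ),
    ("L1624Q", 37): dict(
        density_at_0mV=45.42,
        f_persistent=0.0458,
        tau_onset_table=_scaled_tau_table(_TAU_SCALE_37 / INACT_RATE_FACTOR_LQ_37),
        v_half_inact=-56.0,
    ),
}


def default_phenotype(genotype: str, temperature: float) -> ChannelPhenotype:
    """Packaged phenotype for a supported genotype x temperature condition.

    Parameters
    ----------
    genotype : {"WT", "L1624Q"}
    temperature : {22, 37}
        degC.

    Returns
    -------
    ChannelPhenotype

    Raises
    ------
    UnsupportedConditionError
        If the condition is not one of the four packaged ones.
    """
    key = (str(genotype), int(temperature))
    if key not in _CONDITIONS:
        raise UnsupportedConditionError(
            f"no packaged phenotype for genotype={genotype!r} at "
            f"{temperature} degC; supported: WT/L1624Q at 22/37 degC"
        )
    return ChannelPhenotype(genotype=key[0], temperature=float(key[1]), **_CONDITIONS[key])
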