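"""Reduced-unit <-> physical-unit conversion.

The simulation works in reduced Lennard-Jones-style units: lengths in sigma
(one bead = 10 bp of DNA = 3 nm), energies in eps0 = k_B*T, and time in tau,
the Stokes time of one bead (123 ns at the default parameterisation).  Every
physical number the package reports goes through :class:`UnitSystem` so the
mapping lives in exactly one place.

Output units are the conventional ones of the nanochannel-transport
literature: nm for lengths, ns for times, pN for forces, um/s for drift
speeds, um^2/s for diffusivities and pN*nm for energies.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


#: Boltzmann constant in pN*nm/K.
K_B_PN_NM = 0.0138064852

_KINDS = ("length", "time", "force", "velocity", "diffusivity", "energy")


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and physical units.

    Parameters
    ----------
    sigma_nm : float
        Physical length of 1 sigma in nm (bead diameter; 10 bp of B-DNA).
    temperature_K : float
        Absolute temperature defining eps0 = k_B*T.
    tau_ns : float
        Physical duration of one reduced time unit in ns.
    dt_reduced : float
        Integration step in reduced time units.
    """

    sigma_nm: float = 3.0
    temperature_K: float = 298.0
    tau_ns: float = 123.0
    dt_reduced: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sigma_nm", "temperature_K", "tau_ns", "dt_reduced"):
            if getattr(self, name) <= 0:
                raise ValueError(f"UnitSystem.{name} must be strictly positive")

    @property
    def eps0_pn_nm(self) -> float:
        """Thermal energy eps0 = k_B*T in pN*nm (~4.11 at 298 K)."""
        return K_B_PN_NM * self.temperature_K

    def convert(self, value: float, kind: str) -> float:
        """Convert ``value`` from reduced units to physical units.

        kind -> output unit: length -> nm, time -> ns, force -> pN,
        velocity -> um/s, diffusivity -> um^2/s, energy -> pN*nm.
        Conversion is linear in ``value`` for every kind.
        """
        if kind == "length":
            return value * self.sigma_nm
        if kind == "time":
            return value * self.tau_ns
        if kind == "force":
            # 1 eps0/sigma in pN
            return value * self.eps0_pn_nm / self.sigma_nm
        if kind == "velocity":
            # sigma/tau -> um/s :  (nm/ns) = (um/us) = 1e3 um/s
            return value * (self.sigma_nm / self.tau_ns) * 1e3
        if kind == "diffusivity":
            # sigma^2/tau -> um^2/s : (nm^2/ns) = 1e-6 um^2 / 1e-9 s = 1e3 um^2/s
            return value * (self.sigma_nm**2 / self.tau_ns) * 1e3
        if kind == "energy":
            return value * self.eps0_pn_nm
        raise ValueError(
            f"unknown unit kind {kind!r}; valid kinds are {', '.join(_KINDS)}"
        )

    def to_reduced(self, value: float, kind: str) -> float:
        """Inverse of :meth:`convert` (physical -> reduced)."""
        scale = self.convert(1.0, kind)
        return value / scale

    def steps_to_ms(self, n_steps: int) -> float:
        """Physical duration of ``n_steps`` integration steps in ms."""
        return self.convert(n_steps * self.dt_reduced, "time") * 1e-6

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UnitSystem":
        return cls(**d)


#: Default unit system used throughout unless overridden.
DEFAULT_UNITS = UnitSystem()
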