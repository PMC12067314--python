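"""Model parameters for the burst-and-coast fish-school model.

All quantities are dimensionless: lengths are measured in units of the mean
kick length (about 0.07 m for rummy-nose tetra) and times in units of the
mean kick duration, so the cruising speed scale is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace


@dataclass(frozen=True)
class ModelParams:
    """Constants of the burst-and-coast school model.

    Parameters
    ----------
    gamma_att : float
        Attraction strength. The explored regime is 0-0.6.
    gamma_ali : float
        Alignment strength. The explored regime is 0-1.2.
    l_att, l_ali : float
        Interaction ranges of attraction and alignment, in kick-length
        units. Default 3.
    epsilon : float
        Anisotropy of the alignment response: neighbours ahead of the focal
        fish align it more strongly than neighbours behind. Default 0.8.
    gamma_r : float
        Intensity of the per-kick heading noise. Default 0.2.
    tau0 : float
        Speed relaxation time of the glide, in mean-kick-duration units.
        Default 0.8.
    k : int
        Number of most-influential neighbours a fish interacts with
        (1 or 2).
    n_fish : int
        Group size N.
    kick_mean, kick_sd, kick_min, kick_max : float
        Parameters of the bell-shaped kick length/duration distribution:
        a Gaussian of mean ``kick_mean`` and s.d. ``kick_sd`` truncated to
        ``[kick_min, kick_max]``.  Kick duration and length are set equal
        (unit speed scale).
    noise_mean : float
        Mean of the Gaussian heading-noise variable g.  Default 0 (unbiased
        turning); a nonzero value imposes a systematic per-kick turning
        bias of ``gamma_r * noise_mean``.
    l0_metres : float
        Physical kick length used only when reporting dimensional
        quantities. Default 0.07 m.
    """

    gamma_att: float = 0.0
    gamma_ali: float = 0.0
    l_att: float = 3.0
    l_ali: float = 3.0
    epsilon: float = 0.8
    gamma_r: float = 0.2
    tau0: float = 0.8
    k: int = 1
    n_fish: int = 100
    kick_mean: float = 1.0
    kick_sd: float = 0.25
    kick_min: float = 0.2
    kick_max: float = 2.0
    noise_mean: float = 0.0
    l0_metres: float = field(default=0.07, repr=False)

    def __post_init__(self) -> None:
        for name in ("gamma_att", "gamma_ali", "l_att", "l_ali", "gamma_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k not in (1, 2):
            raise ValueError(f"k must be 1 or 2, got {self.k}")
        if self.n_fish < 1:
            raise ValueError(f"n_fish must be >= 1, got {self.n_fish}")
        if self.tau0 <= 0:
            raise ValueError(f"tau0 must be > 0, got {self.tau0}")
        if self.kick_mean <= 0:
            raise ValueError(f"kick_mean must be > 0, got {self.kick_mean}")
        if self.kick_sd < 0:
            raise ValueError(f"kick_sd must be >= 0, got {self.kick_sd}")
        if not (0 < self.kick_min <= self.kick_mean <= self.kick_max):
            raise ValueError(
                "kick truncation must satisfy 0 < kick_min <= kick_mean <= kick_max, "
                f"got [{self.kick_min}, {self.kick_max}] around {self.kick_mean}"
            )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
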