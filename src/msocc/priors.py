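"""Hyper-prior configuration: the four diffuse/informed scenarios.

Only two hyper-prior means can be informed: the detection-probability
intercept (a beta distribution on the probability scale) and the
occupancy treatment effect (a normal on the logit scale). All other
hyper-means get diffuse normal(0, 10) priors and all hyper-SDs get
uniform(0, 10) priors. The diffuse detection-intercept prior is the
uniform beta(1, 1) on the probability scale, so all four scenarios
share one functional form per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SCENARIOS = (
    "diffuse",
    "informed_detection",
    "informed_treatment",
    "informed_both",
)

#: SD of the diffuse normal hyper-prior on logit-scale hyper-means
DIFFUSE_MU_SD = 10.0
#: upper bound of the uniform hyper-prior on hyper-SDs
SIGMA_UPPER = 10.0


@dataclass
class PriorConfig:
    """One of the four hyper-prior scenarios.

    Parameters
    ----------
    scenario : str
        'diffuse', 'informed_detection', 'informed_treatment' or
        'informed_both'.
    beta_params : (a, b)
        Beta hyper-prior on the detection-intercept hyper-mean,
        probability scale. (1, 1) when that prior is diffuse.
    normal_params : (m, s)
        Normal hyper-prior on the occupancy treatment-effect
        hyper-mean, logit scale. (0, DIFFUSE_MU_SD) when diffuse.
    mu_sd : float
        SD of the diffuse normal(0, mu_sd) prior on every other
        hyper-mean.
    sigma_upper : float
        Upper bound of the uniform(0, sigma_upper) prior on hyper-SDs.
    """

    scenario: str = "diffuse"
    beta_params: tuple = (1.0, 1.0)
    normal_params: tuple = (0.0, DIFFUSE_MU_SD)
    mu_sd: float = DIFFUSE_MU_SD
    sigma_upper: float = SIGMA_UPPER

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        a, b = self.beta_params
        m, s = self.normal_params
        if not (a > 0 and b > 0):
            raise ValueError("beta_params must be positive")
        if not s > 0:
            raise ValueError("normal_params SD must be positive")
        if not (self.mu_sd > 0 and self.sigma_upper > 0):
            raise ValueError("mu_sd and sigma_upper must be positive")
        self.beta_params = (float(a), float(b))
        self.normal_params = (float(m), float(s))

    @property
    def detection_informed(self) -> bool:
        return self.scenario in ("informed_detection", "informed_both")

    @property
    def treatment_informed(self) -> bool:
        return self.scenario in ("informed_treatment", "informed_both")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "beta_params": list(self.beta_params),
            "normal_params": list(self.normal_params),
            "mu_sd": self.mu_sd,
            "sigma_upper": self.sigma_upper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(
            scenario=d.get("scenario", "diffuse"),
            beta_params=tuple(d.get("beta_params", (1.0, 1.0))),
            normal_params=tuple(d.get("normal_params", (0.0, DIFFUSE_MU_SD))),
            mu_sd=float(d.get("mu_sd", DIFFUSE_MU_SD)),
            sigma_upper=float(d.get("sigma_upper", SIGMA_UPPER)),
        )
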