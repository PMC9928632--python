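"""Model parameters: allele frequencies, relative risks, polygenic SD law.

The genetic model combines four biallelic major loci (BRCA2, BRCA1, HOXB13
G84E and a hypothetical residual major gene, recessive by default) with a
normally distributed polygenic component (PGC) whose standard deviation on
the log-hazard scale changes log-linearly with age,

    sigma(t) = sigma70 * r**(t - 70),

and of which a fraction ``alpha`` of the SD is explained by a measured
polygenic score (PGS).  All genetic effects act multiplicatively on the
age-specific baseline hazard.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml


class ParameterError(ValueError):
    """A model-parameter file is missing a field or holds an invalid value."""


@dataclass(frozen=True)
class AgeBandRR:
    """Piecewise-constant relative risk by age.

    ``breaks`` are ascending cut ages; ``values`` has one more entry than
    ``breaks``.  ``values[i]`` applies on ``[breaks[i-1], breaks[i])`` with
    open ends at 0 and infinity.
    """

    breaks: tuple = ()
    values: tuple = (1.0,)

    def __post_init__(self):
        if len(self.values) != len(self.breaks) + 1:
            raise ParameterError("AgeBandRR needs len(values) == len(breaks) + 1")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ParameterError("AgeBandRR breaks must be strictly increasing")
        if any(v <= 0 for v in self.values):
            raise ParameterError("relative risks must be > 0")

    def at(self, age):
        """Relative risk at integer age(s); vectorised."""
        idx = np.searchsorted(np.asarray(self.breaks), np.asarray(age), side="right")
        return np.asarray(self.values)[idx]

    def to_dict(self):
        return {"breaks": list(self.breaks), "values": list(self.values)}

    @classmethod
    def from_value(cls, v):
        if isinstance(v, AgeBandRR):
            return v
        if isinstance(v, (int, float)):
            return cls((), (float(v),))
        return cls(tuple(v["breaks"]), tuple(v["values"]))


@dataclass(frozen=True)
class FemalePenetrance:
    """External breast/ovarian hazard multipliers for BRCA1/2 carriers.

    These are pluggable external inputs (female relatives inform the BRCA
    genotype distribution inside pedigrees); they are deliberately coarse
    stand-ins for published carrier penetrance curves and are not fitted.
    """

    breast_rr_brca1: AgeBandRR = field(default_factory=lambda: AgeBandRR((50,), (17.0, 6.0)))
    breast_rr_brca2: AgeBandRR = field(default_factory=lambda: AgeBandRR((50,), (10.0, 6.0)))
    ovarian_rr_brca1: AgeBandRR = field(default_factory=lambda: AgeBandRR((60,), (30.0, 10.0)))
    ovarian_rr_brca2: AgeBandRR = field(default_factory=lambda: AgeBandRR((60,), (6.0, 4.0)))

    def to_dict(self):
        return {k: getattr(self, k).to_dict() for k in
                ("breast_rr_brca1", "breast_rr_brca2", "ovarian_rr_brca1", "ovarian_rr_brca2")}

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: AgeBandRR.from_value(v) for k, v in d.items()})


REC_MODES = ("recessive", "dominant", "multiplicative")


@dataclass(frozen=True)
class ModelParameters:
    """All tunable quantities of the genetic risk model.

    Frequencies are population allele frequencies (HWE within locus, linkage
    equilibrium across loci).  BRCA1/2 relative-risk curves are externally
    assumed age-band RRs; HOXB13 G84E acts per allele with birth-cohort
    specific RRs (born before/on-or-after 1930); the hypothetical fourth gene
    is recessive by default (``rec_mode`` switches to dominant/multiplicative
    for model comparison).  ``sigma70``/``sd_rate`` parametrise the polygenic
    SD; ``alpha`` is the fraction of that SD explained by the PGS.  Test
    sensitivities give P(positive test | carrier); specificity is perfect.
    """

    f_brca2: float = 0.00102
    f_brca1: float = 0.00064
    f_hoxb13: float = 0.00212
    f_rec: float = 0.12

    rr_brca2: AgeBandRR = field(default_factory=lambda: AgeBandRR((55, 65, 75), (9.0, 6.6, 4.5, 2.8)))
    rr_brca1: AgeBandRR = field(default_factory=lambda: AgeBandRR((65,), (1.8, 1.0)))
    rr_hoxb13_pre1930: float = 2.1
    rr_hoxb13_post1930: float = 3.6
    rr_rec_hom: float = 8.0
    rec_mode: str = "recessive"

    sigma70: float = 2.13
    sd_rate: float = 0.989
    alpha: float = 0.523
    pgs_noise_sd: float = 0.4

    sens_brca2: float = 0.83
    sens_brca1: float = 0.65
    sens_hoxb13: float = 1.0

    female_penetrance: FemalePenetrance = field(default_factory=FemalePenetrance)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self):
        for name in ("f_brca2", "f_brca1", "f_hoxb13", "f_rec"):
            f = getattr(self, name)
            if not (0.0 <= f < 1.0):
                raise ParameterError(f"{name}={f} outside [0, 1)")
        for name in ("rr_hoxb13_pre1930", "rr_hoxb13_post1930", "rr_rec_hom"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.sigma70 <= 0:
            raise ParameterError("sigma70 must be > 0")
        if self.sd_rate <= 0:
            raise ParameterError("sd_rate must be > 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha={self.alpha} outside [0, 1]")
        for name in ("sens_brca2", "sens_brca1", "sens_hoxb13"):
            s = getattr(self, name)
            if not (0.0 < s <= 1.0):
                raise ParameterError(f"{name}={s} outside (0, 1]")
        if self.pgs_noise_sd <= 0:
            raise ParameterError("pgs_noise_sd must be > 0")
        if self.rec_mode not in REC_MODES:
            raise ParameterError(f"rec_mode must be one of {REC_MODES}")

    # -- derived quantities -------------------------------------------------
    def polygenic_sd(self, age):
        """SD of the polygenic component on the log-hazard scale at ``age``."""
        return self.sigma70 * self.sd_rate ** (np.asarray(age, dtype=float) - 70.0)

    def pgs_sd_fractions(self):
        """(fraction of SD explained by PGS, residual fraction).

        The two parts are independent, so variances add:
        (alpha*sigma)**2 + (sqrt(1-alpha^2)*sigma)**2 == sigma**2.
        """
        return self.alpha, math.sqrt(max(0.0, 1.0 - self.alpha ** 2))

    def rr_hoxb13(self, birth_year):
        """Per-allele HOXB13 G84E relative risk for a birth cohort."""
        return self.rr_hoxb13_post1930 if birth_year >= 1930 else self.rr_hoxb13_pre1930

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self):
        d = {}
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, AgeBandRR):
                v = v.to_dict()
            elif isinstance(v, FemalePenetrance):
                v = v.to_dict()
            d[f_.name] = v
        return d

    @classmethod
    def from_dict(cls, d):
        known = {f_.name for f_ in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter fields: {sorted(unknown)}")
        kw = dict(d)
        for name in ("rr_brca2", "rr_brca1"):
            if name in kw:
                kw[name] = AgeBandRR.from_value(kw[name])
        if "female_penetrance" in kw and not isinstance(kw["female_penetrance"], FemalePenetrance):
            kw["female_penetrance"] = FemalePenetrance.from_dict(kw["female_penetrance"])
        return cls(**kw)


def read_parameters(path) -> ModelParameters:
    """Read a YAML/JSON parameter file; raises ParameterError on bad values."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParameterError(f"{path}: expected a mapping of parameter fields")
    return ModelParameters.from_dict(d)


def write_parameters(params: ModelParameters, path):
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
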