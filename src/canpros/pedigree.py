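"""Pedigree data model and the tab-delimited family file dialect.

The file format is a BOADICEA-style columnar text dialect, one row
per individual, tab-separated with a header line::

    FamID IndivID FathID MothID Sex BirthYear CensorAge ProstCa BreastCa \
    OvarianCa Detection BRCA2 BRCA1 HOXB13 PGS Proband

* ``FathID``/``MothID``: ``0`` for a founder (both must be ``0`` or both set).
* ``BirthYear``: calendar year; ``0`` = unknown (a configurable reference
  cohort, 1960 by default, is substituted on read).
* ``CensorAge``: age at last observation (or death), integer years.
* ``ProstCa``/``BreastCa``/``OvarianCa``: ``0`` = unaffected, otherwise the
  integer age at diagnosis.  Ages are half-open years: a diagnosis "at age a"
  falls in ``[a, a+1)``.
* ``Detection``: method of prostate cancer detection for affected men:
  ``S`` symptomatic, ``P`` PSA screen, ``U`` unknown, ``0`` not applicable.
* ``BRCA2``/``BRCA1``/``HOXB13``: genetic test result, ``P`` positive
  (carrier), ``N`` negative (noncarrier), ``0`` untested.
* ``PGS``: standardised polygenic score, ``NA`` if unmeasured.
* ``Proband``: ``1`` marks the proband, ``0`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

GENES = ("BRCA2", "BRCA1", "HOXB13")
DETECTION_MODES = ("symptomatic", "screen", "unknown", "not_applicable")
_DET_CODE = {"S": "symptomatic", "P": "screen", "U": "unknown", "0": "not_applicable"}
_DET_TOKEN = {v: k for k, v in _DET_CODE.items()}
_TEST_CODE = {"P": "carrier", "N": "noncarrier", "0": "untested"}
_TEST_TOKEN = {v: k for k, v in _TEST_CODE.items()}
ASCERTAINMENT_ARMS = ("population", "young_onset", "fh_enriched", "none")

HEADER = ["FamID", "IndivID", "FathID", "MothID", "Sex", "BirthYear", "CensorAge",
          "ProstCa", "BreastCa", "OvarianCa", "Detection",
          "BRCA2", "BRCA1", "HOXB13", "PGS", "Proband"]


class PedigreeError(ValueError):
    """Parse or validation failure; the message names the offending rule."""


@dataclass
class Individual:
    """One pedigree member with phenotypes, test results and PGS."""

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "M"
    birth_year: int = 1960
    censor_age: int = 0
    prostate_dx_age: Optional[int] = None
    breast_dx_age: Optional[int] = None
    ovarian_dx_age: Optional[int] = None
    detection_mode: str = "not_applicable"
    test_results: dict = field(default_factory=lambda: {g: "untested" for g in GENES})
    pgs_z: Optional[float] = None
    is_proband: bool = False

    def validate(self):
        if self.sex not in ("M", "F"):
            raise PedigreeError(f"individual {self.id}: sex must be M or F")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(f"individual {self.id}: both parents present or both absent")
        if self.sex == "M" and (self.breast_dx_age is not None or self.ovarian_dx_age is not None):
            raise PedigreeError(f"individual {self.id}: breast/ovarian diagnoses require sex=F")
        if self.sex == "F" and self.prostate_dx_age is not None:
            raise PedigreeError(f"individual {self.id}: prostate diagnosis requires sex=M")
        for name in ("prostate_dx_age", "breast_dx_age", "ovarian_dx_age"):
            a = getattr(self, name)
            if a is not None and a > self.censor_age:
                raise PedigreeError(f"individual {self.id}: {name}={a} exceeds censor_age={self.censor_age}")
        if self.detection_mode not in DETECTION_MODES:
            raise PedigreeError(f"individual {self.id}: bad detection_mode {self.detection_mode!r}")
        for g, r in self.test_results.items():
            if g not in GENES or r not in _TEST_TOKEN:
                raise PedigreeError(f"individual {self.id}: bad test result {g}={r!r}")

    @property
    def is_founder(self):
        return self.father_id is None

    @property
    def affected(self):
        """Affected with prostate cancer (males only)."""
        return self.prostate_dx_age is not None


class Pedigree:
    """A validated family: members, proband, ascertainment arm."""

    def __init__(self, fam_id, members, proband_id=None, ascertainment_arm="none"):
        self.fam_id = str(fam_id)
        self.members = {m.id: m for m in members}
        if len(self.members) != len(members):
            raise PedigreeError(f"pedigree {fam_id}: duplicate individual ids")
        self.proband_id = proband_id
        if ascertainment_arm not in ASCERTAINMENT_ARMS:
            raise PedigreeError(f"pedigree {fam_id}: bad ascertainment arm {ascertainment_arm!r}")
        self.ascertainment_arm = ascertainment_arm
        self.validate()

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members.values())

    @property
    def proband(self):
        return self.members[self.proband_id] if self.proband_id else None

    def validate(self):
        pid = self.fam_id
        for ind in self:
            ind.validate()
            for par, want in ((ind.father_id, "M"), (ind.mother_id, "F")):
                if par is None:
                    continue
                if par not in self.members:
                    raise PedigreeError(f"pedigree {pid}: parent {par} of {ind.id} not in pedigree")
                if self.members[par].sex != want:
                    raise PedigreeError(f"pedigree {pid}: parent {par} of {ind.id} has wrong sex")
                if par == ind.id:
                    raise PedigreeError(f"pedigree {pid}: {ind.id} is its own parent")
        probands = [m.id for m in self if m.is_proband]
        if self.proband_id is None and len(probands) == 1:
            self.proband_id = probands[0]
        if self.proband_id is not None and self.proband_id not in self.members:
            raise PedigreeError(f"pedigree {pid}: proband {self.proband_id} not in pedigree")
        if self.ascertainment_arm != "none":
            if len(probands) != 1:
                raise PedigreeError(f"pedigree {pid}: exactly one proband required "
                                    f"(found {len(probands)}) for arm {self.ascertainment_arm}")
        self._check_loops()

    def _check_loops(self):
        """Reject marriage/inbreeding loops (and any parent cycles).

        Build the marriage-node graph (individuals + one node per parental
        couple, edges parent--couple and couple--child) and require it to be
        a forest; a cycle in that graph is exactly a pedigree loop.
        """
        parent = {}

        def find(x):
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra == rb:
                return False
            parent[ra] = rb
            return True

        couples = {}
        for ind in self:
            if ind.is_founder:
                continue
            key = (ind.father_id, ind.mother_id)
            if key not in couples:
                cn = ("couple",) + key
                couples[key] = cn
                for p in key:
                    if not union(p, cn):
                        raise PedigreeError(
                            f"pedigree {self.fam_id}: marriage/inbreeding loop involving couple {key}")
            if not union(ind.id, couples[key]):
                raise PedigreeError(
                    f"pedigree {self.fam_id}: marriage/inbreeding loop involving {ind.id}")

    def nuclear_families(self):
        """[(father_id, mother_id, [child ids])] grouped by parental couple."""
        fams = {}
        for ind in self:
            if not ind.is_founder:
                fams.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
        return [(f, m, kids) for (f, m), kids in fams.items()]


# ---------------------------------------------------------------------------
# file I/O

def _parse_age(token, line_no, what):
    try:
        v = int(token)
    except ValueError:
        raise PedigreeError(f"line {line_no}: {what} must be an integer, got {token!r}")
    return None if v == 0 else v


def read_pedigrees(path, default_birth_year=1960):
    """Read the tab-delimited pedigree dialect; returns a list of Pedigree.

    Raises :class:`PedigreeError` naming the line on a malformed row, or the
    pedigree and rule on an invariant violation.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PedigreeError(f"{path}: empty pedigree file")
    header = lines[0].split("\t")
    if header != HEADER:
        raise PedigreeError(f"{path}: bad header; expected {HEADER}")
    fams = {}
    order = []
    for line_no, ln in enumerate(lines[1:], start=2):
        tok = ln.split("\t")
        if len(tok) != len(HEADER):
            raise PedigreeError(f"line {line_no}: expected {len(HEADER)} columns, got {len(tok)}")
        (fam, iid, fid, mid, sex, byear, cage, pca, bca, oca,
         det, t2, t1, th, pgs, prob) = tok
        try:
            birth_year = int(byear)
            censor_age = int(cage)
        except ValueError:
            raise PedigreeError(f"line {line_no}: BirthYear/CensorAge must be integers")
        if det not in _DET_CODE:
            raise PedigreeError(f"line {line_no}: bad Detection code {det!r}")
        tests = {}
        for g, t in zip(GENES, (t2, t1, th)):
            if t not in _TEST_CODE:
                raise PedigreeError(f"line {line_no}: bad {g} test code {t!r}")
            tests[g] = _TEST_CODE[t]
        if pgs in ("NA", "", "-"):
            pgs_z = None
        else:
            try:
                pgs_z = float(pgs)
            except ValueError:
                raise PedigreeError(f"line {line_no}: bad PGS value {pgs!r}")
        ind = Individual(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=sex,
            birth_year=birth_year if birth_year != 0 else default_birth_year,
            censor_age=censor_age,
            prostate_dx_age=_parse_age(pca, line_no, "ProstCa"),
            breast_dx_age=_parse_age(bca, line_no, "BreastCa"),
            ovarian_dx_age=_parse_age(oca, line_no, "OvarianCa"),
            detection_mode=_DET_CODE[det],
            test_results=tests,
            pgs_z=pgs_z,
            is_proband=prob == "1",
        )
        if fam not in fams:
            fams[fam] = []
            order.append(fam)
        fams[fam].append(ind)
    out = []
    for fam in order:
        members = fams[fam]
        arm = "population" if sum(m.is_proband for m in members) == 1 else "none"
        out.append(Pedigree(fam, members, ascertainment_arm=arm))
    return out


def write_pedigrees(pedigrees, path):
    """Write pedigrees in the documented dialect (inverse of read_pedigrees)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HEADER) + "\n")
        for ped in pedigrees:
            for ind in ped:
                row = [
                    ped.fam_id, ind.id,
                    ind.father_id or "0", ind.mother_id or "0",
                    ind.sex, str(ind.birth_year), str(ind.censor_age),
                    str(ind.prostate_dx_age or 0),
                    str(ind.breast_dx_age or 0),
                    str(ind.ovarian_dx_age or 0),
                    _DET_TOKEN[ind.detection_mode],
                    _TEST_TOKEN[ind.test_results.get("BRCA2", "untested")],
                    _TEST_TOKEN[ind.test_results.get("BRCA1", "untested")],
                    _TEST_TOKEN[ind.test_results.get("HOXB13", "untested")],
                    "NA" if ind.pgs_z is None else repr(float(ind.pgs_z)),
                    "1" if ind.is_proband else "0",
                ]
                fh.write("\t".join(row) + "\n")
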