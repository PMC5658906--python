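"""Chemical exposure catalog: identities, detection limits, and inclusion logic.

The packaged catalog describes the 71 biomarkers measured in a pregnancy
cohort: urinary phthalate metabolites and BPA (creatinine-normalized),
serum PFAS, lipid-normalized PCBs, PBDEs and organochlorine pesticides,
two organophosphate pesticide metabolites (DEP, DMP), and two heavy
metals (Pb, Hg).  Each row carries the limit of detection (LOD), the
fraction of samples above the LOD, the geometric mean / geometric
standard deviation of the concentration distribution, and a transcribed
"included in analyses" flag.

Five classes are modelled hierarchically (phthalates+BPA, PFAS, PCBs,
PBDEs, OCPs); the OPPs and metals enter downstream models as ordinary
covariates without hierarchical pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: the seven recognized chemical class labels
CHEM_CLASSES = ("PHTHALATE_BPA", "PCB", "PFAS", "PBDE", "OCP", "OPP", "METAL")

#: the five classes whose coefficients are pooled hierarchically
HIERARCHICAL_CLASSES = ("PHTHALATE_BPA", "PFAS", "PCB", "PBDE", "OCP")

#: classes entering the model as fixed (non-hierarchical) covariates
FIXED_CLASSES = ("OPP", "METAL")


class CatalogError(ValueError):
    """Raised when the catalog file is malformed or fails validation."""


@dataclass(frozen=True)
class ChemicalMeta:
    """One catalog row.

    Parameters
    ----------
    name : str
        Chemical (or metabolite) identifier, e.g. ``"MBP"`` or ``"PCB-153"``.
    chem_class : str
        One of :data:`CHEM_CLASSES`.
    units : str
        Native reporting units (e.g. ``"ug/g creatinine"``).
    lod : float
        Limit of detection in native units (> 0).
    pct_above_lod : float
        Fraction of samples above the LOD, in [0, 1].
    gm : float or None
        Geometric mean concentration; ``None`` when not reported.
    gsd : float or None
        Geometric standard deviation (> 1); ``None`` when not reported.
    included : bool
        Transcribed "included in analyses" flag.
    nhanes_median : float or None
        Median in a contemporaneous US reference population, if available.
    """

    name: str
    chem_class: str
    units: str
    lod: float
    pct_above_lod: float
    gm: Optional[float]
    gsd: Optional[float]
    included: bool
    nhanes_median: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise CatalogError(
                f"{self.name}: unknown chem_class {self.chem_class!r}"
            )
        if not self.lod > 0:
            raise CatalogError(f"{self.name}: lod must be > 0, got {self.lod}")
        if not 0.0 <= self.pct_above_lod <= 1.0:
            raise CatalogError(
                f"{self.name}: pct_above_lod must lie in [0, 1], "
                f"got {self.pct_above_lod}"
            )
        if self.gsd is not None and not self.gsd > 1.0:
            raise CatalogError(f"{self.name}: gsd must be > 1, got {self.gsd}")
        if self.included and (self.gm is None or self.gsd is None):
            raise CatalogError(
                f"{self.name}: included chemicals need gm and gsd"
            )

    @property
    def hierarchical(self) -> bool:
        """Whether this chemical's class is pooled hierarchically."""
        return self.chem_class in HIERARCHICAL_CLASSES

    @property
    def lod_native(self) -> float:
        """LOD on the same scale as the concentration values.

        The lipid-normalized classes (PCBs, PBDEs, OCPs) report
        concentrations in ng/g lipid but their LODs in pg/g, so those
        LODs are divided by 1000 here; all other classes print both on
        the same scale.
        """
        if self.chem_class in ("PCB", "PBDE", "OCP"):
            return self.lod / 1000.0
        return self.lod

    @property
    def ln_gm(self) -> float:
        """Natural-log geometric mean (ln-scale location)."""
        if self.gm is None:
            raise ValueError(f"{self.name}: gm not available")
        return math.log(self.gm)

    @property
    def ln_gsd(self) -> float:
        """Natural-log geometric standard deviation (ln-scale spread)."""
        if self.gsd is None:
            raise ValueError(f"{self.name}: gsd not available")
        return math.log(self.gsd)


def default_catalog_path() -> Path:
    """Path to the catalog CSV shipped inside the package."""
    return Path(resources.files("edcmix") / "data" / "chemical_catalog.csv")


def _parse_optional_float(value, name: str, row: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise CatalogError(f"row {row!r}: bad {name} value {value!r}") from exc


def load_catalog(path: Optional[str | Path] = None) -> list[ChemicalMeta]:
    """Load the chemical catalog from ``path`` (default: packaged file).

    Returns one :class:`ChemicalMeta` per catalog row, preserving file
    order.  Rows whose reference-median cell was not reported carry
    ``nhanes_median=None``.

    Raises
    ------
    CatalogError
        On a malformed row (naming the row) or a duplicate chemical name.
    """
    src = Path(path) if path is not None else default_catalog_path()
    expected = [
        "name", "chem_class", "units", "lod", "pct_above_lod",
        "gm", "gsd", "included", "nhanes_median",
    ]
    df = pd.read_csv(src, dtype={"name": str, "chem_class": str, "units": str})
    if list(df.columns) != expected:
        raise CatalogError(
            f"catalog columns {list(df.columns)} != expected {expected}"
        )

    entries: list[ChemicalMeta] = []
    seen: set[str] = set()
    for _, rec in df.iterrows():
        name = str(rec["name"])
        if name in seen:
            raise CatalogError(f"duplicate chemical name {name!r}")
        seen.add(name)
        included_raw = rec["included"]
        if isinstance(included_raw, str):
            if included_raw.strip().lower() not in {"true", "false"}:
                raise CatalogError(f"row {name!r}: bad included flag {included_raw!r}")
            included = included_raw.strip().lower() == "true"
        else:
            included = bool(included_raw)
        try:
            entry = ChemicalMeta(
                name=name,
                chem_class=str(rec["chem_class"]),
                units=str(rec["units"]),
                lod=float(rec["lod"]),
                pct_above_lod=float(rec["pct_above_lod"]),
                gm=_parse_optional_float(rec["gm"], "gm", name),
                gsd=_parse_optional_float(rec["gsd"], "gsd", name),
                included=included,
                nhanes_median=_parse_optional_float(
                    rec["nhanes_median"], "nhanes_median", name
                ),
            )
        except CatalogError:
            raise
        except (TypeError, ValueError) as exc:
            raise CatalogError(f"malformed row {name!r}: {exc}") from exc
        entries.append(entry)
    return entries


def apply_inclusion(
    catalog: Sequence[ChemicalMeta],
    mode: str = "flag",
    threshold: float = 0.90,
) -> tuple[list[ChemicalMeta], list[ChemicalMeta]]:
    """Partition the catalog into hierarchical exposures and fixed covariates.

    Parameters
    ----------
    mode : {"flag", "rule"}
        ``"flag"`` uses the transcribed inclusion column; ``"rule"``
        includes chemicals with ``pct_above_lod >= threshold``.  The two
        modes genuinely disagree on this catalog (several flagged-in
        chemicals are well below 90% detection); use
        :func:`inclusion_mode_difference` to inspect the discrepancy.
    threshold : float
        Detection-fraction cutoff for ``mode="rule"``.

    Returns
    -------
    (hierarchical_exposures, fixed_covariates)
        Included chemicals from the five hierarchical classes, and the
        included OPPs and metals.  The partition is disjoint and covers
        every included entry.
    """
    if mode not in {"flag", "rule"}:
        raise ValueError(f"unknown inclusion mode {mode!r}")

    def is_in(c: ChemicalMeta) -> bool:
        if mode == "flag":
            return c.included
        return c.pct_above_lod >= threshold

    selected = [c for c in catalog if is_in(c)]
    hier = [c for c in selected if c.chem_class in HIERARCHICAL_CLASSES]
    fixed = [c for c in selected if c.chem_class in FIXED_CLASSES]
    return hier, fixed


def inclusion_mode_difference(
    catalog: Sequence[ChemicalMeta], threshold: float = 0.90
) -> dict[str, list[str]]:
    """Symmetric difference between flag-based and rule-based inclusion.

    Returns a dict with keys ``"flag_only"`` (flagged in but below the
    detection rule) and ``"rule_only"`` (meeting the rule but flagged out).
    """
    flag = {c.name for c in catalog if c.included}
    rule = {c.name for c in catalog if c.pct_above_lod >= threshold}
    order = [c.name for c in catalog]
    return {
        "flag_only": [n for n in order if n in flag - rule],
        "rule_only": [n for n in order if n in rule - flag],
    }


def class_counts(entries: Iterable[ChemicalMeta]) -> dict[str, int]:
    """Number of entries per chemical class (classes present only)."""
    out: dict[str, int] = {}
    for c in entries:
        out[c.chem_class] = out.get(c.chem_class, 0) + 1
    return out
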