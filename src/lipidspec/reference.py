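"""Reference-side quantities computed from GC fatty-acid compositions.

Implements the iodine value, FA class sums (SFA/MUFA/PUFA, EPA+DHA), and the
conversion between proportional contents (% of total FA) and absolute
contents (% of sample), which are related through the total fat content.

The iodine value (IV, g I₂ per 100 g fat) of a composition is the linear
functional

    IV = Mw(I₂) · Σᵢ #DB(i) · V(i) / Mw(FAMe(i))

where V(i) is the proportional content (in percent) of fatty acid i, #DB(i)
its number of carbon–carbon double bonds and Mw(FAMe(i)) the molecular
weight of its methyl ester.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import CompositionTable

MW_IODINE = 253.81  # g/mol, I₂

# Atomic weights used to derive methyl-ester molecular weights from formulas.
_MW_C, _MW_H, _MW_O = 12.011, 1.008, 15.999

EPA = "C20-5 (n-3)"
DHA = "C22-6 (n-3)"


def methyl_ester_mw(n_carbons: int, n_double_bonds: int) -> float:
    """Molecular weight (g/mol) of the methyl ester of an acyl chain.

    An FA with ``n_carbons`` acyl carbons and D double bonds esterifies to
    C_{n+1} H_{2(n+1)−2D} O₂ (e.g. C18:1 → C₁₉H₃₆O₂ = 296.49 g/mol).
    """
    c = n_carbons + 1
    h = 2 * c - 2 * n_double_bonds
    return c * _MW_C + h * _MW_H + 2 * _MW_O


def _class_for(n_double_bonds: int) -> str:
    if n_double_bonds == 0:
        return "SFA"
    if n_double_bonds == 1:
        return "MUFA"
    return "PUFA"


@dataclass(frozen=True)
class FattyAcidDefinition:
    """Identity of one fatty acid: unsaturation and methyl-ester weight."""

    name: str
    n_carbons: int
    n_double_bonds: int
    methyl_ester_mw: float

    def __post_init__(self) -> None:
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be ≥ 0")
        if self.methyl_ester_mw <= 0:
            raise ValueError("methyl_ester_mw must be positive")

    @property
    def fa_class(self) -> str:
        return _class_for(self.n_double_bonds)

    @classmethod
    def from_formula(cls, name: str, n_carbons: int, n_double_bonds: int) -> "FattyAcidDefinition":
        return cls(name, n_carbons, n_double_bonds,
                   methyl_ester_mw(n_carbons, n_double_bonds))


def builtin_definitions() -> dict[str, FattyAcidDefinition]:
    """Definitions for the 13 fatty acids modelled throughout the package.

    Methyl-ester weights are computed from molecular formulas; they can be
    overridden by loading a YAML definitions file instead.
    """
    chains = [
        ("C14-0", 14, 0),
        ("C16-0", 16, 0),
        ("C18-0", 18, 0),
        ("C16-1 (n-7)", 16, 1),
        ("C18-1 (n-9)", 18, 1),
        ("C18-1 (n-7)", 18, 1),
        ("C20-1 (n-9)", 20, 1),
        ("C22-1 (n-11)", 22, 1),
        ("C18-2 (n-6)", 18, 2),
        ("C18-3 (n-3)", 18, 3),
        (EPA, 20, 5),
        ("C22-5 (n-3)", 22, 5),
        (DHA, 22, 6),
    ]
    return {name: FattyAcidDefinition.from_formula(name, c, d) for name, c, d in chains}


def load_definitions(path: str | Path) -> dict[str, FattyAcidDefinition]:
    """Load FA definitions from YAML: ``{name: {n_carbons, n_double_bonds[, methyl_ester_mw]}}``."""
    raw = yaml.safe_load(Path(path).read_text())
    defs = {}
    for name, entry in raw.items():
        mw = entry.get("methyl_ester_mw")
        if mw is None:
            mw = methyl_ester_mw(entry["n_carbons"], entry["n_double_bonds"])
        defs[name] = FattyAcidDefinition(name, entry["n_carbons"], entry["n_double_bonds"], mw)
    return defs


def save_definitions(defs: Mapping[str, FattyAcidDefinition], path: str | Path) -> None:
    out = {
        d.name: {"n_carbons": d.n_carbons, "n_double_bonds": d.n_double_bonds,
                 "methyl_ester_mw": float(d.methyl_ester_mw)}
        for d in defs.values()
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def _resolve(v: Mapping[str, float] | pd.Series) -> pd.Series:
    return pd.Series(dict(v), dtype=float) if not isinstance(v, pd.Series) else v.astype(float)


def iodine_value(v: Mapping[str, float] | pd.Series,
                 defs: Mapping[str, FattyAcidDefinition],
                 mw_iodine: float = MW_IODINE) -> float:
    """Iodine value (g I₂ / 100 g) of one proportional composition (in %)."""
    v = _resolve(v)
    missing = [n for n in v.index if n not in defs]
    if missing:
        raise KeyError(f"no fatty-acid definition for: {missing}")
    total = 0.0
    for name, pct in v.items():
        d = defs[name]
        total += d.n_double_bonds * pct / d.methyl_ester_mw
    return mw_iodine * total


def iodine_values(table: CompositionTable,
                  defs: Mapping[str, FattyAcidDefinition],
                  mw_iodine: float = MW_IODINE) -> pd.Series:
    """Iodine value per sample of a composition table."""
    db_over_mw = np.array([defs[n].n_double_bonds / defs[n].methyl_ester_mw
                           for n in table.fa_names])
    vals = table.values.to_numpy() @ db_over_mw * mw_iodine
    return pd.Series(vals, index=table.values.index, name="iodine_value")


def fa_features(v: Mapping[str, float] | pd.Series,
                defs: Mapping[str, FattyAcidDefinition]) -> dict[str, float | None]:
    """Class sums and EPA+DHA for one composition.

    Returns a dict with keys ``SFA``, ``MUFA``, ``PUFA`` and ``EPA_DHA``.
    EPA_DHA is ``None`` (missing, not zero) when either EPA or DHA is not a
    column of the composition.
    """
    v = _resolve(v)
    missing = [n for n in v.index if n not in defs]
    if missing:
        raise KeyError(f"no fatty-acid definition for: {missing}")
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for name, pct in v.items():
        sums[defs[name].fa_class] += float(pct)
    out: dict[str, float | None] = dict(sums)
    if EPA in v.index and DHA in v.index:
        out["EPA_DHA"] = float(v[EPA] + v[DHA])
    else:
        out["EPA_DHA"] = None
    return out


def feature_table(table: CompositionTable,
                  defs: Mapping[str, FattyAcidDefinition],
                  include_iv: bool = True) -> pd.DataFrame:
    """Per-sample FA features (class sums, EPA+DHA, optionally iodine value)."""
    rows = [fa_features(table.values.loc[i], defs) for i in table.values.index]
    df = pd.DataFrame(rows, index=table.values.index)
    if include_iv:
        df["iodine_value"] = iodine_values(table, defs)
    return df


def to_absolute(v, fat):
    """Proportional contents (% of total FA) → absolute contents (% of sample)."""
    v = np.asarray(v, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if np.any(fat <= 0):
        raise ValueError("fat must be positive")
    return v * fat / 100.0


def to_proportional(absolute, fat):
    """Absolute contents (% of sample) → proportional contents (% of total FA)."""
    absolute = np.asarray(absolute, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if np.any(fat == 0):
        raise ValueError("fat of 0 cannot carry nonzero absolute content")
    if np.any(fat < 0):
        raise ValueError("fat must be positive")
    return absolute * 100.0 / fat


def absolute_table(table: CompositionTable) -> pd.DataFrame:
    """All FA columns converted to absolute contents (% of sample)."""
    fat = table.fat.to_numpy()[:, None]
    return pd.DataFrame(table.values.to_numpy() * fat / 100.0,
                        index=table.values.index, columns=table.fa_names)
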