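"""ICD-10 code normalization and prefix-based code maps.

Claims extracts from Chinese county insurance databases carry extended
ICD-10 codes such as ``I25.103`` (coronary atherosclerotic heart disease)
or ``R42.x00`` (vertigo and dizziness): a standard 3-character rubric plus
a local 3-digit extension.  All matching in this package therefore runs on
dot-stripped, upper-cased codes and uses longest-prefix semantics, so that
a 3-to-5 character category prefix (e.g. ``I25``) captures every local
extension beneath it.

Three code systems are used downstream, all expressed as :class:`CodeMap`:

* ``ADRG`` — adjacent diagnosis-related groups (CHS-DRG style), grouping
  principal diagnoses into clinically coherent categories;
* ``Elixhauser`` — chronic comorbidity categories;
* ``PQI`` — ambulatory-care-sensitive conditions used to flag potentially
  preventable hospitalizations.

Packaged default maps (structurally equivalent stand-ins for the real
CHS-DRG / Elixhauser / PQI lists, which can be swapped via config) live in
``hicost/data/``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "normalize_icd10",
    "CodeMap",
    "classify_code",
    "load_code_map",
    "packaged_map_path",
    "load_packaged_map",
]

_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]*$")


class CodeValidationError(ValueError):
    """Raised for codes or maps that violate the documented format."""


def normalize_icd10(code: str) -> str:
    """Return the canonical (upper-case, dot-free) form of an ICD-10 code.

    >>> normalize_icd10("I25.103")
    'I25103'
    >>> normalize_icd10("j18.000 ")
    'J18000'
    """
    if not isinstance(code, str) or not code.strip():
        raise CodeValidationError(f"empty or non-string ICD-10 code: {code!r}")
    canon = code.strip().replace(".", "").upper()
    if not _ICD10_RE.match(canon):
        raise CodeValidationError(
            f"code {code!r} (normalized {canon!r}) does not match the "
            "ICD-10 pattern letter+digit+alphanumerics"
        )
    return canon


@dataclass(frozen=True)
class CodeMap:
    """A named mapping from ICD-10 code prefixes to category labels.

    ``entries`` maps normalized prefixes to category labels.  Loading
    rejects ambiguous maps: no entry may be a proper prefix of another
    entry that carries a different category, so longest-prefix matching is
    well defined.
    """

    name: str
    entries: dict[str, str] = field(default_factory=dict)
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        if self.match_mode not in ("prefix", "exact"):
            raise CodeValidationError(f"unknown match_mode {self.match_mode!r}")
        normd = {}
        for prefix, category in self.entries.items():
            normd[normalize_icd10(prefix)] = str(category)
        object.__setattr__(self, "entries", normd)
        if self.match_mode == "prefix":
            self._check_ambiguity()
        # prefixes sorted longest-first for matching
        object.__setattr__(
            self, "_ordered", sorted(self.entries, key=len, reverse=True)
        )

    def _check_ambiguity(self) -> None:
        keys = sorted(self.entries)
        for i, short in enumerate(keys):
            for long in keys[i + 1 :]:
                if not long.startswith(short):
                    break
                if long != short and self.entries[long] != self.entries[short]:
                    raise CodeValidationError(
                        f"map {self.name!r} is ambiguous: {short!r} -> "
                        f"{self.entries[short]!r} is a proper prefix of "
                        f"{long!r} -> {self.entries[long]!r}"
                    )

    @property
    def categories(self) -> list[str]:
        """Distinct category labels, sorted."""
        return sorted(set(self.entries.values()))

    def classify(self, code: str) -> str | None:
        """Longest-prefix category for a normalized code, or None."""
        if self.match_mode == "exact":
            return self.entries.get(code)
        for prefix in self._ordered:
            if code.startswith(prefix):
                return self.entries[prefix]
        return None

    def classify_many(self, codes: pd.Series) -> pd.Series:
        """Vectorized classification: one lookup per distinct code."""
        uniq = codes.dropna().unique()
        lut = {c: self.classify(c) for c in uniq}
        return codes.map(lut)


def classify_code(code: str, code_map: CodeMap) -> str | None:
    """Classify a normalized ICD-10 code under a loaded map."""
    return code_map.classify(code)


def load_code_map(path: str | Path, name: str | None = None) -> CodeMap:
    """Load a CodeMap from a CSV with columns ``prefix, category[, system]``."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"prefix", "category"} - set(df.columns)
    if missing:
        raise CodeValidationError(
            f"code-map file {path} is missing columns: {sorted(missing)}"
        )
    entries = dict(zip(df["prefix"], df["category"]))
    return CodeMap(name=name or path.stem, entries=entries)


def packaged_map_path(which: str) -> Path:
    """Path of a packaged default map: 'adrg', 'elixhauser' or 'pqi'."""
    fname = {"adrg": "adrg_map.csv", "elixhauser": "elixhauser_map.csv", "pqi": "pqi_map.csv"}
    if which not in fname:
        raise KeyError(f"no packaged map {which!r}; choose from {sorted(fname)}")
    return Path(str(resources.files("hicost.data") / fname[which]))


def load_packaged_map(which: str) -> CodeMap:
    """Load one of the packaged default maps by short name."""
    return load_code_map(packaged_map_path(which), name=which)
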