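"""Strain x marker genotype matrices for single-spore-isolate populations.

Scores use a four-letter alphabet: ``a`` (band matching the reference parent),
``b`` (band matching the donor parent), ``h`` (both bands -- a heterokaryotic
strain carrying both nuclear types) and ``-`` (unclear / missing).  Mapping
requires a homokaryon-only population, so strains showing the two-band code at
any screening marker are excluded before linkage analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = frozenset("abh-")

__all__ = ["GenotypeMatrix", "classify_strains", "filter_population",
           "segregation_test", "segregation_table"]


class GenotypeMatrix:
    """Rectangular strains x markers score table over {a, b, h, -}.

    Thin wrapper around a pandas DataFrame (rows = strains, columns =
    markers) that enforces the code alphabet and unique marker ids.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            raise ValueError("marker ids must be unique")
        if data.index.duplicated().any():
            raise ValueError("strain ids must be unique")
        if len(data):
            bad = set(np.unique(data.to_numpy(dtype="U1"))) - set("abh-")
            if bad:
                raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        self.data = data.astype("U1") if len(data) else data

    # -- basic protocol ----------------------------------------------------
    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeMatrix) and self.data.equals(other.data)

    def column(self, marker: str) -> pd.Series:
        return self.data[marker]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """TSV: header row = marker ids, first column = strain id."""
        self.data.to_csv(path, sep="\t", index_label="strain")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="strain", dtype=str)
        return cls(df)

    def to_mapmaker_raw(self, path) -> None:
        """Export in MAPMAKER/EXP ``.raw`` layout, coding a/b as backcross
        alleles (A/B); h and - become missing ('-')."""
        n, m = self.shape
        code = {"a": "A", "b": "B", "h": "-", "-": "-"}
        with open(path, "w") as fh:
            fh.write("data type f2 backcross\n")
            fh.write(f"{n} {m} 0\n")
            for marker in self.markers:
                calls = "".join(code[c] for c in self.data[marker])
                fh.write(f"*{marker} {calls}\n")


def classify_strains(matrix: GenotypeMatrix, screening_markers: list[str],
                     ) -> dict[str, list[str]]:
    """Split strains into homokaryons / heterokaryons / undetermined.

    A strain showing the two-band code ``h`` at any screening marker is
    heterokaryotic; a strain with only missing calls at every screening
    marker is undetermined.  The result is invariant to marker and strain
    order.
    """
    unknown = set(screening_markers) - set(matrix.markers)
    if unknown:
        raise KeyError(f"unknown screening markers: {sorted(unknown)}")
    if not screening_markers:
        raise ValueError("need at least one screening marker")
    sub = matrix.data[list(screening_markers)].to_numpy(dtype="U1")
    het = (sub == "h").any(axis=1)
    undet = (sub == "-").all(axis=1) & ~het
    strains = np.asarray(matrix.strains)
    return {
        "homokaryons": sorted(strains[~het & ~undet]),
        "heterokaryons": sorted(strains[het]),
        "undetermined": sorted(strains[undet]),
    }


def filter_population(matrix: GenotypeMatrix,
                      screening_markers: list[str] | None = None,
                      ) -> tuple[GenotypeMatrix, dict]:
    """Reduce the matrix to the homokaryon mapping population.

    By default every marker screens (a strain with an ``h`` call anywhere is
    treated as heterokaryotic).  Residual ``h`` calls in retained strains are
    scoring artefacts and are coerced to ``-``; the count is reported.
    """
    screen = list(screening_markers) if screening_markers else matrix.markers
    cls = classify_strains(matrix, screen)
    keep = [s for s in matrix.strains if s in set(cls["homokaryons"])]
    if not keep:
        raise ValueError("no homokaryotic strains remain")
    sub = matrix.data.loc[keep].copy()
    n_coerced = int((sub.to_numpy(dtype="U1") == "h").sum())
    if n_coerced:
        sub = sub.replace("h", "-")
    info = {"n_heterokaryons": len(cls["heterokaryons"]),
            "n_undetermined": len(cls["undetermined"]),
            "n_homokaryons": len(keep),
            "n_coerced_h": n_coerced}
    return GenotypeMatrix(sub), info


def segregation_test(matrix: GenotypeMatrix, marker: str,
                     min_calls: int = 10) -> tuple[float, float]:
    """Chi-square test (1 df) of 1:1 a:b segregation at one marker.

    Missing and two-band calls are excluded.
    """
    col = matrix.data[marker].to_numpy(dtype="U1")
    n_a = int((col == "a").sum())
    n_b = int((col == "b").sum())
    n = n_a + n_b
    if n < min_calls:
        raise ValueError(f"only {n} scored calls at {marker} (< {min_calls})")
    chi2, p = stats.chisquare([n_a, n_b])
    return float(chi2), float(p)


def segregation_table(matrix: GenotypeMatrix, min_calls: int = 10,
                      max_missing: float = 0.2, min_p: float = 1e-3,
                      ) -> pd.DataFrame:
    """Per-marker QC: 1:1 segregation and missingness.

    Markers exceeding ``max_missing`` or with segregation p below ``min_p``
    are flagged, not dropped.
    """
    rows = []
    n_strains = len(matrix.strains)
    for m in matrix.markers:
        col = matrix.data[m].to_numpy(dtype="U1")
        n_a, n_b = int((col == "a").sum()), int((col == "b").sum())
        missing = 1.0 - (n_a + n_b) / n_strains if n_strains else 1.0
        if n_a + n_b >= min_calls:
            chi2, p = segregation_test(matrix, m, min_calls)
        else:
            chi2, p = np.nan, np.nan
        rows.append({"marker": m, "n_a": n_a, "n_b": n_b,
                     "missing_frac": round(missing, 4),
                     "chi2": chi2, "p": p,
                     "flagged": bool(missing > max_missing
                                     or (p == p and p < min_p))})
    return pd.DataFrame(rows)
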