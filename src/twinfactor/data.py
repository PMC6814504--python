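"""Twin-pair data containers and wide-CSV input/output.

The unit of analysis is the twin pair.  A :class:`TwinSample` holds one
zygosity group as an ``n_pairs x 2 x p`` phenotype array plus pair-level
covariates; a :class:`TwinStudy` bundles the MZ and DZ groups, which every
biometric fit requires jointly.  The design is complete-pairs: missing
values are rejected at construction.

The on-disk format is one row per pair:
``pair_id, zygosity, sex, age, <var>_t1, <var>_t2, ...``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TwinSample", "TwinStudy", "read_twin_csv", "write_twin_csv"]


@dataclass
class TwinSample:
    """One zygosity group of twin pairs.

    phenotypes has shape (n_pairs, 2, p): pair, twin within pair, variable.
    sex and age are pair-level (both members of a generated pair share them).
    """

    zygosity: str
    phenotypes: np.ndarray
    variables: list[str]
    sex: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {self.zygosity!r}")
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.phenotypes.ndim != 3 or self.phenotypes.shape[1] != 2:
            raise ValueError("phenotypes must have shape (n_pairs, 2, p)")
        if self.phenotypes.shape[2] != len(self.variables):
            raise ValueError("variable-name count does not match phenotype array")
        if len(self.variables) < 1:
            raise ValueError("need at least one variable")
        if np.isnan(self.phenotypes).any():
            raise ValueError("missing values are not allowed (complete-pairs design)")
        for name in ("sex", "age"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_pairs,):
                    raise ValueError(f"{name} must be pair-level with length n_pairs")
                setattr(self, name, arr)

    @property
    def n_pairs(self) -> int:
        return self.phenotypes.shape[0]

    def pair_array(self, variable: str) -> np.ndarray:
        """n_pairs x 2 array for one variable."""
        j = self.variables.index(variable)
        return self.phenotypes[:, :, j]

    def stacked(self, variables: list[str] | None = None) -> np.ndarray:
        """n_pairs x 2p array: [vars of twin 1, vars of twin 2]."""
        variables = variables or self.variables
        idx = [self.variables.index(v) for v in variables]
        return np.hstack([self.phenotypes[:, 0, idx], self.phenotypes[:, 1, idx]])

    def moments(self, variables: list[str] | None = None) -> tuple[np.ndarray, np.ndarray, int]:
        """(biased covariance, mean vector, n) of the stacked twin-pair layout."""
        X = self.stacked(variables)
        S = np.cov(X, rowvar=False, bias=True)
        return np.atleast_2d(S), X.mean(axis=0), self.n_pairs


@dataclass
class TwinStudy:
    """MZ and DZ groups measured on an identical variable set."""

    mz: TwinSample
    dz: TwinSample

    def __post_init__(self) -> None:
        if self.mz.zygosity != "MZ" or self.dz.zygosity != "DZ":
            raise ValueError("TwinStudy requires an MZ sample and a DZ sample, in that order")
        if self.mz.variables != self.dz.variables:
            raise ValueError("MZ and DZ groups must share an identical variable set")

    @property
    def variables(self) -> list[str]:
        return self.mz.variables

    @property
    def groups(self) -> tuple[TwinSample, TwinSample]:
        return (self.mz, self.dz)

    def children_frame(self) -> pd.DataFrame:
        """Long per-child frame (two rows per pair) for pooled, child-level analyses."""
        frames = []
        for g in self.groups:
            for t in range(2):
                df = pd.DataFrame(g.phenotypes[:, t, :], columns=g.variables)
                df.insert(0, "twin", t + 1)
                df.insert(0, "pair_id", [f"{g.zygosity}{i}" for i in range(g.n_pairs)])
                df.insert(1, "zygosity", g.zygosity)
                if g.sex is not None:
                    df["sex"] = g.sex
                if g.age is not None:
                    df["age"] = g.age
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def select(self, variables: list[str]) -> "TwinStudy":
        """Study restricted to (and reordered by) the given variables."""
        idx_m = [self.mz.variables.index(v) for v in variables]
        idx_d = [self.dz.variables.index(v) for v in variables]
        return TwinStudy(
            mz=TwinSample("MZ", self.mz.phenotypes[:, :, idx_m], list(variables), self.mz.sex, self.mz.age),
            dz=TwinSample("DZ", self.dz.phenotypes[:, :, idx_d], list(variables), self.dz.sex, self.dz.age),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            df = pd.DataFrame({"pair_id": [f"{g.zygosity}{i}" for i in range(g.n_pairs)]})
            df["zygosity"] = g.zygosity
            df["sex"] = g.sex if g.sex is not None else np.nan
            df["age"] = g.age if g.age is not None else np.nan
            for j, v in enumerate(g.variables):
                df[f"{v}_t1"] = g.phenotypes[:, 0, j]
                df[f"{v}_t2"] = g.phenotypes[:, 1, j]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def write_twin_csv(study: TwinStudy, path: str | Path) -> None:
    """Write a study to the wide pair-per-row CSV layout."""
    study.to_frame().to_csv(path, index=False)


def _sample_from_frame(df: pd.DataFrame, zygosity: str, variables: list[str]) -> TwinSample:
    sub = df[df["zygosity"] == zygosity]
    if sub.empty:
        raise ValueError(f"no {zygosity} pairs in file")
    n = len(sub)
    phen = np.empty((n, 2, len(variables)))
    for j, v in enumerate(variables):
        phen[:, 0, j] = sub[f"{v}_t1"].to_numpy(dtype=float)
        phen[:, 1, j] = sub[f"{v}_t2"].to_numpy(dtype=float)
    sex = sub["sex"].to_numpy(dtype=float) if "sex" in sub else None
    age = sub["age"].to_numpy(dtype=float) if "age" in sub else None
    if sex is not None and np.isnan(sex).all():
        sex = None
    if age is not None and np.isnan(age).all():
        age = None
    return TwinSample(zygosity, phen, list(variables), sex, age)


def read_twin_csv(path: str | Path, variables: list[str] | None = None) -> TwinStudy:
    """Read a wide twin CSV; variables default to every ``<var>_t1/_t2`` pair found."""
    df = pd.read_csv(path)
    if "zygosity" not in df.columns:
        raise ValueError("twin CSV must contain a 'zygosity' column")
    if variables is None:
        variables = [c[:-3] for c in df.columns if c.endswith("_t1")]
        missing = [v for v in variables if f"{v}_t2" not in df.columns]
        if missing:
            raise ValueError(f"unpaired twin columns for: {missing}")
    else:
        for v in variables:
            for suffix in ("_t1", "_t2"):
                if f"{v}{suffix}" not in df.columns:
                    raise ValueError(f"column {v}{suffix} not found")
    return TwinStudy(
        mz=_sample_from_frame(df, "MZ", variables),
        dz=_sample_from_frame(df, "DZ", variables),
    )
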