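"""Replicate-level phenotype tables: data model, I/O and aggregation.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with columns ``genotype, row_type, treatment, replicate, trait, value``
wrapped in :class:`PhenotypeTable`, which validates the closed treatment set,
non-negativity and (optionally) balance.  Missing values are explicit NaN,
never zero-filled; balanced-design operations downstream refuse unbalanced
cells rather than impute.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import FormatError, PhenomicsWarning, ValidationError
from .traits import (
    REGISTRY,
    TREATMENT_ALIASES,
    TREATMENTS,
    GenotypeMeta,
)

LONG_COLUMNS = ["genotype", "row_type", "treatment", "replicate", "trait", "value"]
KEY_COLUMNS = ["genotype", "treatment", "replicate"]


def _resolve_treatment(label: object) -> str:
    lab = str(label).strip()
    try:
        return TREATMENT_ALIASES[lab]
    except KeyError:
        raise ValidationError(
            f"unknown treatment label {lab!r}; expected one of "
            f"{sorted(set(TREATMENT_ALIASES))}"
        ) from None


class PhenotypeTable:
    """Balanced (or explicitly unbalanced) replicate-level trait observations.

    Parameters
    ----------
    data
        Long-format frame with columns ``genotype, row_type, treatment,
        replicate, trait, value``.  ``value`` may be NaN (explicit missing)
        but never negative or infinite.
    meta
        Optional mapping genotype -> :class:`GenotypeMeta`; reconstructed
        from the ``row_type`` column when omitted.
    provenance
        Free-text source description (file path or simulation spec hash).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        meta: Optional[Mapping[str, GenotypeMeta]] = None,
        provenance: str = "",
    ) -> None:
        missing_cols = [c for c in LONG_COLUMNS if c not in data.columns]
        if missing_cols:
            raise FormatError(f"missing key column(s): {', '.join(missing_cols)}")
        df = data.loc[:, LONG_COLUMNS].copy()
        df["genotype"] = df["genotype"].astype(str).str.strip()
        df["row_type"] = df["row_type"].astype(str).str.strip()
        df["trait"] = df["trait"].astype(str).str.strip()
        df["treatment"] = df["treatment"].map(_resolve_treatment)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="coerce").astype(float)

        bad = df["value"].notna() & ((df["value"] < 0) | ~np.isfinite(df["value"]))
        if bad.any():
            first = df.loc[bad].iloc[0]
            raise ValidationError(
                "negative or non-finite value at "
                f"(genotype={first['genotype']}, treatment={first['treatment']}, "
                f"replicate={first['replicate']}, trait={first['trait']}): "
                f"{first['value']}"
            )
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must start at 1")

        self.data = df.reset_index(drop=True)
        self.provenance = provenance
        if meta is None:
            meta = {
                g: GenotypeMeta(name=g, row_type=rt)
                for g, rt in df.drop_duplicates("genotype")
                .set_index("genotype")["row_type"]
                .items()
            }
        self.meta = dict(meta)

    # -- basic accessors ---------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def treatments(self) -> list[str]:
        present = set(self.data["treatment"].unique())
        return [t for t in TREATMENTS if t in present]

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def row_type(self, genotype: str) -> str:
        return self.meta[genotype].row_type

    def subset(self, row_type: Optional[str] = None,
               traits: Optional[Iterable[str]] = None) -> "PhenotypeTable":
        df = self.data
        if row_type is not None:
            df = df[df["row_type"] == row_type]
        if traits is not None:
            df = df[df["trait"].isin(list(traits))]
        meta = {g: m for g, m in self.meta.items() if g in set(df["genotype"])}
        return PhenotypeTable(df, meta=meta, provenance=self.provenance)

    def __len__(self) -> int:
        return len(self.data)

    # -- balance bookkeeping ----------------------------------------------

    def balance_report(self) -> pd.DataFrame:
        """Replicate counts per (genotype, treatment, trait) cell,
        counting only non-missing values."""
        d = self.data.dropna(subset=["value"])
        return (
            d.groupby(["genotype", "treatment", "trait"], sort=True)
            .size()
            .rename("n")
            .reset_index()
        )

    @property
    def balanced(self) -> bool:
        counts = self.balance_report()["n"]
        return len(counts) > 0 and counts.nunique() == 1 and (
            len(self.balance_report())
            == len(self.genotypes) * len(self.treatments) * len(self.traits)
        )

    def require_balance(self) -> int:
        """Return the common replicate count or raise with the deficient cells."""
        from .exceptions import BalanceError

        rep = self.balance_report()
        if rep.empty:
            raise BalanceError("empty table")
        r = int(rep["n"].max())
        expected = len(self.genotypes) * len(self.treatments) * len(self.traits)
        if rep["n"].nunique() != 1 or len(rep) != expected:
            deficient = rep[rep["n"] < r]
            raise BalanceError(
                f"unbalanced design: {len(deficient)} deficient cell(s), e.g. "
                f"{deficient.head(3).to_dict('records')}"
            )
        return r

    # -- aggregation -------------------------------------------------------

    def cell_means(self, trait: str) -> pd.DataFrame:
        """Genotype x treatment matrix of replicate means for one trait.

        Each entry is the arithmetic mean over the replicate values of that
        (genotype, treatment) cell; the replicate itself is already the mean
        of the four plants in a pot.  Cells with no observation are NaN and
        reported with a warning, never filled.
        """
        if trait not in set(self.data["trait"]):
            raise KeyError(f"trait {trait!r} not present in table")
        d = self.data[self.data["trait"] == trait]
        mat = d.pivot_table(
            index="genotype", columns="treatment", values="value", aggfunc="mean"
        )
        mat = mat.reindex(index=self.genotypes, columns=self.treatments)
        if mat.isna().any().any():
            missing = [
                (g, t) for g in mat.index for t in mat.columns
                if pd.isna(mat.loc[g, t])
            ]
            warnings.warn(
                f"cell_means({trait}): {len(missing)} empty cell(s): "
                f"{missing[:5]}",
                PhenomicsWarning,
                stacklevel=2,
            )
        return mat

    # -- serialization -----------------------------------------------------

    def write(self, path: str | Path) -> Path:
        """Write the long-format CSV; inverse of :func:`read_phenotype_table`."""
        path = Path(path)
        out = self.data.copy()
        out.to_csv(path, index=False)
        return path

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.data.sort_values(LONG_COLUMNS[:-1]).reset_index(drop=True)
        b = other.data.sort_values(LONG_COLUMNS[:-1]).reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# readers / writers


def read_phenotype_table(path: str | Path, layout: str = "long") -> PhenotypeTable:
    """Read a phenotype table from CSV or XLSX.

    Parameters
    ----------
    path
        CSV (or ``.xlsx``) file.  Long layout has columns
        ``genotype,row_type,treatment,replicate,trait,value``; wide layout has
        one column per trait after the key columns
        ``genotype,row_type,treatment,replicate``.
    layout
        ``"long"`` or ``"wide"``.

    Unknown (unregistered) trait columns in a wide file are ignored with a
    warning.  A table with unequal replicate counts is returned with
    ``balanced == False`` and a warning listing the deficient cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")

    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        frames = []
        for name, df in sheets.items():
            if "treatment" not in df.columns and len(sheets) > 1:
                # one-sheet-per-treatment dialect: sheet name is the label
                df = df.copy()
                df["treatment"] = name
            frames.append(df)
        raw = pd.concat(frames, ignore_index=True)
    else:
        raw = pd.read_csv(path)

    raw.columns = [str(c).strip() for c in raw.columns]

    if layout == "long":
        missing = [c for c in LONG_COLUMNS if c not in raw.columns]
        if missing:
            raise FormatError(f"missing key column(s): {', '.join(missing)}")
        long_df = raw[LONG_COLUMNS]
    else:
        key = KEY_COLUMNS + ["row_type"]
        missing = [c for c in key if c not in raw.columns]
        if missing:
            raise FormatError(f"missing key column(s): {', '.join(missing)}")
        trait_cols = [c for c in raw.columns if c not in key]
        known = [c for c in trait_cols if c in REGISTRY]
        unknown = [c for c in trait_cols if c not in REGISTRY]
        if unknown:
            warnings.warn(
                f"ignoring unregistered trait column(s): {unknown}",
                PhenomicsWarning,
                stacklevel=2,
            )
        long_df = raw.melt(
            id_vars=key, value_vars=known, var_name="trait", value_name="value"
        )

    table = PhenotypeTable(long_df, provenance=str(path))
    if not table.balanced:
        rep = table.balance_report()
        r = rep["n"].max() if not rep.empty else 0
        deficient = rep[rep["n"] < r]
        warnings.warn(
            f"table is unbalanced; deficient cells: "
            f"{deficient.head(5).to_dict('records')}",
            PhenomicsWarning,
            stacklevel=2,
        )
    return table


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> Path:
    """Long-format CSV writer; ``read_phenotype_table(write(x)) == x``."""
    return table.write(path)


# ---------------------------------------------------------------------------
# derived traits

#: Default derivation formulas.  Each maps a derived code to (components,
#: function over the component replicate values).  Denominator zero yields
#: an explicit missing value, never infinity.
DEFAULT_FORMULAS: dict[str, tuple[tuple[str, ...], Callable[..., float]]] = {
    "MTKW": (("MSW", "MSN"), lambda msw, msn: 1000.0 * msw / msn),
    "ATKW": (("MSW", "SSW", "MSN", "SSN"),
             lambda msw, ssw, msn, ssn: 1000.0 * (msw + ssw) / (msn + ssn)),
    "ASN": (("MSN", "SSN", "RT"), lambda msn, ssn, rt: (msn + ssn) / rt),
    "ASW": (("MSW", "SSW", "RT"), lambda msw, ssw, rt: (msw + ssw) / rt),
}


def derive_traits(
    table: PhenotypeTable,
    formulas: Optional[Mapping[str, tuple[tuple[str, ...], Callable[..., float]]]] = None,
    strict: bool = False,
) -> PhenotypeTable:
    """Add the computed traits (MTKW, ATKW, ASN, ASW) at replicate level.

    Traits already present as measured values are left untouched (derivation
    skipped with a warning); zero denominators record the value as missing
    with a warning.  Traits whose components are absent are skipped with a
    warning unless ``strict`` is set.  The operation is idempotent.
    """
    formulas = dict(DEFAULT_FORMULAS if formulas is None else formulas)
    present = set(table.data["trait"])
    wide = table.data.pivot_table(
        index=["genotype", "row_type", "treatment", "replicate"],
        columns="trait",
        values="value",
        aggfunc="first",
    )
    new_rows = []
    for code, (components, fn) in formulas.items():
        if code in present:
            warnings.warn(
                f"derived trait {code} already measured; derivation skipped",
                PhenomicsWarning,
                stacklevel=2,
            )
            continue
        missing_comp = [c for c in components if c not in wide.columns]
        if missing_comp:
            if strict:
                raise ValidationError(
                    f"cannot derive {code}: component trait(s) {missing_comp} absent"
                )
            warnings.warn(
                f"cannot derive {code}: component trait(s) {missing_comp} "
                "absent; skipped",
                PhenomicsWarning,
                stacklevel=2,
            )
            continue
        args = [wide[c] for c in components]
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = fn(*args)
        vals = pd.Series(np.asarray(vals, dtype=float), index=wide.index)
        n_bad = int((~np.isfinite(vals.to_numpy()) & wide[components[0]].notna().to_numpy()).sum())
        if n_bad:
            warnings.warn(
                f"derive {code}: {n_bad} zero-denominator cell(s) recorded as missing",
                PhenomicsWarning,
                stacklevel=2,
            )
        vals = vals.where(np.isfinite(vals))
        block = vals.rename("value").reset_index()
        block["trait"] = code
        new_rows.append(block[LONG_COLUMNS])
    if not new_rows:
        return table
    out = pd.concat([table.data] + new_rows, ignore_index=True)
    return PhenotypeTable(out, meta=table.meta, provenance=table.provenance)
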