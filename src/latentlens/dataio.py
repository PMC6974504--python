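"""Reading and writing tidy-format metabolomics peak tables and result artifacts.

A peak table is stored either as a two-sheet XLSX workbook (a *Data* sheet of
samples x metabolites plus metadata columns, and a *Peak* sheet of
per-metabolite metadata including QC columns when available) or as the
equivalent pair of CSV files.  Missing concentrations are kept as missing
values throughout -- a zero is a valid concentration, never a missingness
sentinel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class PeakTableError(ValueError):
    """Raised when a peak table fails structural validation."""


@dataclass
class PeakTable:
    """A samples x metabolites concentration matrix with class labels.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per sample (row of ``X``).
    class_labels : ndarray of int
        Binary outcome per sample; the positive class (case) is coded 1 and
        the reference class (control) 0.
    X : ndarray of float, shape (N, M)
        Metabolite concentrations; missing entries are NaN.
    metabolite_names : list of str
        One label per metabolite (column of ``X``).
    qc_rsd : ndarray, optional
        Per-metabolite relative standard deviation (%) across pooled QC
        replicates, used by the feature-cleaning filter.
    perc_missing : ndarray, optional
        Per-metabolite percentage of missing measurements.
    """

    sample_ids: list
    class_labels: np.ndarray
    X: np.ndarray
    metabolite_names: list
    qc_rsd: Optional[np.ndarray] = None
    perc_missing: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.class_labels = np.asarray(self.class_labels)
        n, m = self.X.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise PeakTableError(
                f"sample metadata length mismatch: X has {n} rows, "
                f"{len(self.sample_ids)} sample ids, {len(self.class_labels)} labels"
            )
        if len(self.metabolite_names) != m:
            raise PeakTableError(
                f"{len(self.metabolite_names)} metabolite names for {m} columns"
            )
        uniq = np.unique(self.class_labels)
        if not np.array_equal(np.sort(uniq), [0, 1]):
            raise PeakTableError(
                f"class labels must contain exactly the two values 0 and 1, got {uniq}"
            )
        self.class_labels = self.class_labels.astype(int)
        for name, arr in (("qc_rsd", self.qc_rsd), ("perc_missing", self.perc_missing)):
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (m,):
                    raise PeakTableError(f"{name} must have length {m}, got {arr.shape}")
                if np.nanmin(arr) < 0:
                    raise PeakTableError(f"{name} must be non-negative")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.X.shape[1]

    def subset_samples(self, idx) -> "PeakTable":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            class_labels=self.class_labels[idx],
            X=self.X[idx],
        )

    def subset_metabolites(self, idx) -> "PeakTable":
        idx = np.asarray(idx)
        return replace(
            self,
            X=self.X[:, idx],
            metabolite_names=[self.metabolite_names[i] for i in idx],
            qc_rsd=None if self.qc_rsd is None else self.qc_rsd[idx],
            perc_missing=None if self.perc_missing is None else self.perc_missing[idx],
        )


def _map_classes(raw, positive_class):
    raw = pd.Series(raw)
    uniq = sorted(raw.dropna().unique().tolist(), key=str)
    if len(uniq) != 2:
        raise PeakTableError(f"class column must be binary, found values {uniq}")
    if positive_class is None:
        if set(uniq) == {0, 1}:
            return raw.astype(int).to_numpy()
        raise PeakTableError(
            f"class values {uniq} are not 0/1; specify positive_class explicitly"
        )
    if positive_class not in uniq:
        raise PeakTableError(f"positive_class {positive_class!r} not among {uniq}")
    return (raw == positive_class).astype(int).to_numpy()


def read_peak_table(
    path,
    peak_path=None,
    data_sheet: str = "Data",
    peak_sheet: str = "Peak",
    sample_col: str = "SampleID",
    class_col: str = "Class",
    name_col: str = "Name",
    qc_rsd_col: str = "QC_RSD",
    perc_missing_col: str = "Perc_missing",
    positive_class=None,
) -> PeakTable:
    """Read a tidy peak table from XLSX (two sheets) or CSV (two files).

    The data sheet holds one row per sample with a sample-id column, a class
    column and one column per metabolite; the peak sheet holds one row per
    metabolite with its name and, when available, QC relative standard
    deviation and percent-missing columns.  ``positive_class`` names the
    class label mapped to 1 (required unless labels are already 0/1).
    """
    path = os.fspath(path)
    if path.endswith((".xlsx", ".xls")):
        data = pd.read_excel(path, sheet_name=data_sheet)
        try:
            peak = pd.read_excel(path, sheet_name=peak_sheet)
        except ValueError:
            peak = None
    else:
        data = pd.read_csv(path, float_precision="round_trip")
        peak = pd.read_csv(peak_path) if peak_path is not None else None

    if class_col not in data.columns:
        raise PeakTableError(f"data sheet has no class column {class_col!r}")
    if sample_col not in data.columns:
        raise PeakTableError(f"data sheet has no sample-id column {sample_col!r}")

    meta_cols = {sample_col, class_col}
    metabolite_names = [c for c in data.columns if c not in meta_cols]
    X = data[metabolite_names].apply(pd.to_numeric, errors="coerce").to_numpy(float)

    qc_rsd = perc_missing = None
    if peak is not None:
        if name_col not in peak.columns:
            raise PeakTableError(f"peak sheet has no name column {name_col!r}")
        peak_names = peak[name_col].astype(str).tolist()
        if peak_names != [str(m) for m in metabolite_names]:
            missing = set(map(str, metabolite_names)) ^ set(peak_names)
            raise PeakTableError(
                f"metabolite names differ between data and peak sheets: {sorted(missing)}"
            )
        if qc_rsd_col in peak.columns:
            qc_rsd = peak[qc_rsd_col].to_numpy(float)
        if perc_missing_col in peak.columns:
            perc_missing = peak[perc_missing_col].to_numpy(float)

    return PeakTable(
        sample_ids=data[sample_col].astype(str).tolist(),
        class_labels=_map_classes(data[class_col], positive_class),
        X=X,
        metabolite_names=metabolite_names,
        qc_rsd=qc_rsd,
        perc_missing=perc_missing,
    )


def write_peak_table(pt: PeakTable, path, data_sheet="Data", peak_sheet="Peak",
                     sample_col="SampleID", class_col="Class") -> None:
    """Write a PeakTable as a two-sheet XLSX workbook or a CSV pair.

    For a CSV target ``path`` receives the data table and a sibling file with
    suffix ``_peak.csv`` receives the metabolite metadata.
    """
    data = pd.DataFrame(pt.X, columns=pt.metabolite_names)
    data.insert(0, class_col, pt.class_labels)
    data.insert(0, sample_col, pt.sample_ids)
    peak = pd.DataFrame({"Name": pt.metabolite_names})
    if pt.qc_rsd is not None:
        peak["QC_RSD"] = pt.qc_rsd
    if pt.perc_missing is not None:
        peak["Perc_missing"] = pt.perc_missing
    path = os.fspath(path)
    if path.endswith((".xlsx", ".xls")):
        with pd.ExcelWriter(path) as xw:
            data.to_excel(xw, sheet_name=data_sheet, index=False)
            peak.to_excel(xw, sheet_name=peak_sheet, index=False)
    else:
        data.to_csv(path, index=False)
        peak.to_csv(path.replace(".csv", "") + "_peak.csv", index=False)


def write_results(contribution_tables, evaluation_summary, outdir) -> list:
    """Write contribution tables and an evaluation summary as CSV files.

    ``contribution_tables`` maps metric names to ContributionTable objects
    (anything with metabolite_names/values/ci_low/ci_high/significant);
    ``evaluation_summary`` is a flat mapping of metric name to value.
    Returns the manifest: the list of file paths written.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = []
    for metric, tab in contribution_tables.items():
        df = pd.DataFrame(
            {
                "metabolite": tab.metabolite_names,
                "median": tab.values,
                "ci_lower": tab.ci_low,
                "ci_upper": tab.ci_high,
                "significant": np.asarray(tab.significant, dtype=bool),
            }
        )
        fp = os.path.join(outdir, f"contribution_{metric}.csv")
        df.to_csv(fp, index=False)
        manifest.append(fp)
    if evaluation_summary is not None:
        fp = os.path.join(outdir, "evaluation_summary.csv")
        pd.DataFrame([evaluation_summary]).to_csv(fp, index=False)
        manifest.append(fp)
    return manifest
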