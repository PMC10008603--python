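"""TSV/CSV readers and writers plus the report file set.

Canonical dialect is tab-separated UTF-8 with '.' decimals; comma-separated
files are accepted on read (by extension).  Missing markers are the empty
string and "NA".  The WSI modality travels as a long-format table with one
row per patch: ``patient_id, patch_rank, density, e0..e{D-1}``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ablation import AblationReport, aggregate_by_arity
from .containers import DOMAINS, ModalityMatrix, SurvivalTable, ValidationError
from .wsi import PatchBag

_NA = ["", "NA"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_modality_table(path, modality: str, domain: str | None = None) -> ModalityMatrix:
    """Read a patient x feature table and validate its value domain."""
    path = Path(path)
    domain = domain or DOMAINS.get(modality, "continuous")
    try:
        df = pd.read_csv(path, sep=_sep(path), na_values=_NA, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if df.empty or df.shape[1] < 2:
        raise ValidationError(f"{path}: no data rows or no feature columns")
    if df.columns[0] != "patient_id":
        raise ValidationError(f"{path}: first column must be 'patient_id'")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate patient id {dup.iloc[0]!r}")
    values = df.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        col = bad.any().idxmax()
        raise ValidationError(f"{path}: non-numeric cell in column {col!r}")
    m = ModalityMatrix(
        modality,
        df["patient_id"].astype(str).to_numpy(dtype=object),
        df.columns[1:].to_numpy(dtype=object),
        numeric.to_numpy(dtype=float),
        domain,
    )
    _check_domain(m, path)
    return m


def _check_domain(m: ModalityMatrix, path) -> None:
    v = m.values[~np.isnan(m.values)]
    if m.domain == "cnv5" and not np.isin(v, (-2.0, -1.0, 0.0, 1.0, 2.0)).all():
        raise ValidationError(f"{path}: cnv values outside {{-2..2}}")
    if m.domain == "beta" and ((v < 0) | (v > 1)).any():
        raise ValidationError(f"{path}: methylation beta values outside [0,1]")
    if m.domain == "nonneg" and (v < 0).any():
        raise ValidationError(f"{path}: negative values in non-negative domain")
    if not np.isfinite(v).all():
        raise ValidationError(f"{path}: non-finite values")


def write_modality_table(m: ModalityMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.to_frame().to_csv(path, sep=_sep(path), index=False, na_rep="NA")


def read_survival_table(path) -> SurvivalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), na_values=_NA, keep_default_na=False)
    need = {"patient_id", "time_months", "event"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: survival table needs columns {sorted(need)}")
    return SurvivalTable(
        df["patient_id"].astype(str).to_numpy(dtype=object),
        df["time_months"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )


def write_survival_table(s: SurvivalTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    s.to_frame().to_csv(path, sep=_sep(path), index=False)


def write_wsi_bags(bags: dict[str, PatchBag], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in sorted(bags):
        b = bags[pid]
        for rank in range(b.n_patches):
            rows.append([pid, rank, b.density[rank], *b.patches[rank]])
    dim = next(iter(bags.values())).patches.shape[1] if bags else 0
    cols = ["patient_id", "patch_rank", "density"] + [f"e{j}" for j in range(dim)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep(path), index=False)


def read_wsi_bags(path) -> dict[str, PatchBag]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    need = {"patient_id", "patch_rank", "density"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: WSI table needs columns {sorted(need)}")
    emb_cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    emb_cols.sort(key=lambda c: int(c[1:]))
    bags = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("patch_rank")
        bags[str(pid)] = PatchBag(
            patient_id=str(pid),
            patches=grp[emb_cols].to_numpy(dtype=float),
            density=grp["density"].to_numpy(dtype=float),
        )
    return bags


# ---------------------------------------------------------------------------
# reports


def _table2_style(report: AblationReport) -> pd.DataFrame:
    """Metric-per-row layout: one block per arity, classifier x kind columns."""
    agg = aggregate_by_arity(report)
    long = agg.melt(
        id_vars=["arity", "feature_kind", "classifier"],
        value_vars=["mean_acc", "mean_f1", "mean_sn", "mean_pre"],
        var_name="metric",
        value_name="value",
    )
    long["metric"] = long["metric"].str.replace("mean_", "", regex=False)
    order = {"acc": 0, "f1": 1, "sn": 2, "pre": 3}
    wide = long.pivot_table(
        index=["arity", "metric"], columns=["classifier", "feature_kind"], values="value"
    )
    wide = wide.reset_index()
    wide["_ord"] = wide["metric"].map(order)
    wide = wide.sort_values(["arity", "_ord"]).drop(columns="_ord")
    wide.columns = [
        "_".join(c) if isinstance(c, tuple) and c[1] else (c[0] if isinstance(c, tuple) else c)
        for c in wide.columns
    ]
    return wide


def config_fingerprint(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_report(report: AblationReport, out_dir, manifest: dict | None = None) -> dict[str, Path]:
    """Write records.csv, aggregates.json, table2_style.csv, run_manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "aggregates": out / "aggregates.json",
        "table2_style": out / "table2_style.csv",
        "manifest": out / "run_manifest.json",
    }
    report.to_frame().to_csv(paths["records"], index=False)
    agg = aggregate_by_arity(report)
    paths["aggregates"].write_text(json.dumps(agg.to_dict(orient="records"), indent=1))
    _table2_style(report).to_csv(paths["table2_style"], index=False)
    manifest = dict(manifest or {})
    manifest.setdefault("n_records", len(report.records))
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return paths
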