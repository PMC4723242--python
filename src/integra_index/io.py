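"""CSV and posterior-file input/output.

All tabular interchange is UTF-8 comma-separated CSV with a header row;
service-code *sets* inside a cell are semicolon-delimited.  Readers
validate aggressively: unknown service codes and malformed rows are
reported with line numbers, duplicated contact rows are dropped with a
warning.  Posteriors round-trip through ``.npz`` plus a JSON metadata
sidecar embedded in the archive.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTE_NAMES, ClientContact, ClientVisit, FacilityInventory, group_contacts
from .cfa import ModelSpec, Posterior, SamplerConfig
from .ordinalize import IndicatorMatrix, OrdinalizationScheme
from .scoring import FactorScores

FLOW_COLUMNS = ("facility_id", "day", "client_id", "provider_id", "services", "referrals")


class InputError(ValueError):
    """Malformed or invalid input file contents."""


def _split_codes(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(c.strip() for c in text.split(";") if c.strip())


def read_client_flow(path: str | Path, allow_overlap: bool = False) -> list[ClientVisit]:
    """Read a client-flow contact CSV into grouped per-day visits.

    Row-level problems are aggregated into one error listing line numbers
    (line 1 is the header).  Exact duplicate contact rows are dropped with
    a warning.  By default a service appearing in both ``services`` and
    ``referrals`` of one contact is an error.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")

    n_before = len(df)
    df = df.drop_duplicates(subset=list(FLOW_COLUMNS))
    if len(df) < n_before:
        warnings.warn(f"{path}: dropped {n_before - len(df)} duplicate contact rows", stacklevel=2)

    contacts: list[ClientContact] = []
    errors: list[str] = []
    for pos, row in df.iterrows():
        line = pos + 2  # header is line 1
        try:
            services = _split_codes(row["services"])
            referrals = _split_codes(row["referrals"])
            contact = ClientContact(
                facility_id=str(row["facility_id"]),
                day=int(row["day"]),
                client_id=str(row["client_id"]),
                provider_id=str(row["provider_id"]),
                services_received=services,
                referrals=referrals,
            )
            if not allow_overlap and services & referrals:
                raise ValueError(
                    f"codes {sorted(services & referrals)} both received and referred"
                )
            contacts.append(contact)
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise InputError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors[:20]))
    return group_contacts(contacts)


def write_client_flow(contacts: pd.DataFrame, path: str | Path) -> None:
    contacts.to_csv(path, index=False, columns=list(FLOW_COLUMNS))


_INVENTORY_FILES = {
    "unit_services": ("unit_services.csv", ("facility_id", "services")),
    "facility_services": ("facility_services.csv", ("facility_id", "services")),
    "room_logs": ("room_logs.csv", ("facility_id", "room_id", "services")),
    "staff_logs": ("staff_logs.csv", ("facility_id", "staff_id", "services")),
}


def read_inventories(directory: str | Path) -> dict[str, FacilityInventory]:
    """Read the four inventory CSVs from a directory.

    Missing files are tolerated (the corresponding attributes come out
    missing downstream); missing *rows* for a facility likewise.
    """
    directory = Path(directory)
    parts: dict[str, pd.DataFrame] = {}
    for key, (fname, cols) in _INVENTORY_FILES.items():
        fpath = directory / fname
        if not fpath.exists():
            warnings.warn(f"{fpath} not found; {key} will be missing", stacklevel=2)
            continue
        df = pd.read_csv(fpath, dtype=str)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise InputError(f"{fpath}: missing required columns {missing}")
        parts[key] = df

    facilities: set[str] = set()
    for df in parts.values():
        facilities |= set(df["facility_id"])
    out: dict[str, FacilityInventory] = {}
    for fac in sorted(facilities):
        unit = facility = None
        if "unit_services" in parts:
            rows = parts["unit_services"].query("facility_id == @fac")
            if len(rows):
                unit = frozenset().union(*(_split_codes(s) for s in rows["services"]))
        if "facility_services" in parts:
            rows = parts["facility_services"].query("facility_id == @fac")
            if len(rows):
                facility = frozenset().union(*(_split_codes(s) for s in rows["services"]))
        room_logs = {}
        if "room_logs" in parts:
            for _, r in parts["room_logs"].query("facility_id == @fac").iterrows():
                room_logs[str(r["room_id"])] = _split_codes(r["services"])
        staff_logs = {}
        if "staff_logs" in parts:
            for _, r in parts["staff_logs"].query("facility_id == @fac").iterrows():
                staff_logs[str(r["staff_id"])] = _split_codes(r["services"])
        try:
            out[fac] = FacilityInventory(
                facility_id=fac,
                unit_services=unit,
                facility_services=facility,
                room_logs=room_logs,
                staff_logs=staff_logs,
            )
        except ValueError as exc:
            raise InputError(f"inventory for facility {fac}: {exc}") from exc
    return out


def write_inventories(inventories: Mapping[str, FacilityInventory], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    unit_rows, fac_rows, room_rows, staff_rows = [], [], [], []
    for fac, inv in inventories.items():
        if inv.unit_services is not None:
            unit_rows.append({"facility_id": fac, "services": ";".join(sorted(inv.unit_services))})
        if inv.facility_services is not None:
            fac_rows.append(
                {"facility_id": fac, "services": ";".join(sorted(inv.facility_services))}
            )
        for room, codes in inv.room_logs.items():
            room_rows.append(
                {"facility_id": fac, "room_id": room, "services": ";".join(sorted(codes))}
            )
        for staff, codes in inv.staff_logs.items():
            staff_rows.append(
                {"facility_id": fac, "staff_id": staff, "services": ";".join(sorted(codes))}
            )
    pd.DataFrame(unit_rows).to_csv(directory / "unit_services.csv", index=False)
    pd.DataFrame(fac_rows).to_csv(directory / "facility_services.csv", index=False)
    pd.DataFrame(room_rows).to_csv(directory / "room_logs.csv", index=False)
    pd.DataFrame(staff_rows).to_csv(directory / "staff_logs.csv", index=False)


def write_attribute_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_attribute_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("facility_id", "wave", *ATTRIBUTE_NAMES) if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing attribute-table columns {missing}")
    return df


def write_indicator_matrix(matrix: IndicatorMatrix, path: str | Path) -> None:
    """Indicator CSV plus a ``.meta.json`` sidecar with categories/cutpoints."""
    path = Path(path)
    matrix.data.reset_index().to_csv(path, index=False)
    meta = {
        "n_categories": matrix.n_categories,
        "scheme": json.loads(matrix.scheme.to_json()) if matrix.scheme else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_indicator_matrix(path: str | Path) -> IndicatorMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    index_cols = [c for c in ("facility_id", "wave") if c in df.columns]
    df = df.set_index(index_cols)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        n_categories = {k: int(v) for k, v in meta["n_categories"].items()}
        scheme = (
            OrdinalizationScheme.from_json(json.dumps(meta["scheme"])) if meta["scheme"] else None
        )
    else:
        warnings.warn(f"{meta_path} not found; inferring category counts from data", stacklevel=2)
        n_categories = {c: int(df[c].max()) + 1 for c in df.columns}
        scheme = None
    return IndicatorMatrix(data=df.astype(float), n_categories=n_categories, scheme=scheme)


def save_posterior(post: Posterior, path: str | Path) -> None:
    """Persist draws and provenance in one ``.npz`` archive."""
    idx = post.facility_index
    if isinstance(idx, pd.MultiIndex):
        index_records = [list(map(str, tup)) for tup in idx]
        index_names = [str(n) for n in idx.names]
    else:
        index_records = [[str(v)] for v in idx]
        index_names = [str(idx.name or "facility_id")]
    meta = {
        "indicators": post.indicators,
        "n_categories": post.n_categories,
        "n_factors": post.spec.n_factors,
        "loading_pattern": dict(post.spec.loading_pattern),
        "config": {
            "n_chains": post.config.n_chains,
            "n_iterations": post.config.n_iterations,
            "burn_in_fraction": post.config.burn_in_fraction,
            "thin": post.config.thin,
            "seed": post.config.seed,
            "handle_missing": post.config.handle_missing,
        },
        "index_names": index_names,
        "index_records": index_records,
        "sign_resolved": post.sign_resolved,
    }
    arrays = {"lam": post.lam, "eta": post.eta}
    for j, t in enumerate(post.tau):
        arrays[f"tau_{j}"] = t
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_posterior(path: str | Path) -> Posterior:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        lam = data["lam"]
        eta = data["eta"]
        tau = [data[f"tau_{j}"] for j in range(len(meta["indicators"]))]
    records = meta["index_records"]
    names = meta["index_names"]
    if len(names) > 1:
        index = pd.MultiIndex.from_tuples([tuple(r) for r in records], names=names)
    else:
        index = pd.Index([r[0] for r in records], name=names[0])
    spec = ModelSpec(n_factors=meta["n_factors"], loading_pattern=meta["loading_pattern"])
    config = SamplerConfig(**meta["config"])
    return Posterior(
        spec=spec,
        config=config,
        indicators=list(meta["indicators"]),
        n_categories={k: int(v) for k, v in meta["n_categories"].items()},
        facility_index=index,
        lam=lam,
        tau=tau,
        eta=eta,
        sign_resolved=bool(meta["sign_resolved"]),
    )


def write_scores(scores: FactorScores, path: str | Path) -> None:
    scores.data.to_csv(path, index=False)


def read_scores(path: str | Path) -> FactorScores:
    df = pd.read_csv(path)
    missing = [c for c in ("facility_id", "factor", "score") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing score columns {missing}")
    return FactorScores(data=df)
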