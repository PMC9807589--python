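"""Feature-table CSV and model-file persistence.

Feature tables are plain CSV with header ``label,c1,...,cI`` — one row per
realization, 1-based feature indices.  Trained classifiers serialize to a
versioned JSON document carrying every parameter needed to reproduce
classification bit-identically after reload (dictionary, means, coordinate
functions, variances, degeneracy flags, density samples and bandwidths),
plus provenance (training row counts and a content hash).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np

from .canonical import CanonicalModel, Monomial, _decision_indices, build_dictionary
from .classifier import ClassModel, Criterion, DiagnosticClassifier
from .density import KernelDensity
from .errors import InvalidInputError, ParseError, SchemaVersionError
from .moments import Standardization, TrainingSet

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def read_feature_table(path) -> list[TrainingSet]:
    """Parse a labelled feature CSV into per-class training sets.

    Grouping is by label; group order follows sorted labels, row order
    within a group follows the file.  Malformed headers, ragged rows and
    non-numeric cells raise :class:`ParseError` citing the line number.
    """
    path = Path(path)
    groups: dict[str, list[list[float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2 or header[0] != "label" or any(
            h != f"c{i}" for i, h in enumerate(header[1:], start=1)
        ):
            raise ParseError(
                f"{path}: line 1: expected header 'label,c1,...,cI', got {header!r}"
            )
        width = len(header) - 1
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {width + 1} columns, "
                    f"got {len(row)}"
                )
            try:
                vals = [float(cell) for cell in row[1:]]
            except ValueError:
                bad = next(c for c in row[1:] if not _is_float(c))
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric cell {bad!r}"
                ) from None
            if not all(np.isfinite(vals)):
                raise ParseError(f"{path}: line {lineno}: non-finite value")
            groups.setdefault(row[0], []).append(vals)
    if not groups:
        raise ParseError(f"{path}: no data rows")
    return [
        TrainingSet(label, np.asarray(rows, dtype=float))
        for label, rows in sorted(groups.items())
    ]


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_feature_table(path, sets: list[TrainingSet]) -> None:
    """Write per-class realizations to the standard labelled CSV."""
    if not sets:
        raise InvalidInputError("write_feature_table: nothing to write")
    width = sets[0].n_features
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label"] + [f"c{i}" for i in range(1, width + 1)])
        for ts in sets:
            for row in ts.values:
                writer.writerow([ts.label] + [repr(float(v)) for v in row])


def _model_payload(clf: DiagnosticClassifier, seed=None) -> dict:
    order = clf.classes[0].model.order
    payload = {
        "schema_version": SCHEMA_VERSION,
        "criterion": {
            "kind": clf.criterion.kind,
            "order": clf.criterion.order,
            "degree_bound": clf.criterion.degree_bound,
        },
        "I": order.I,
        "N": order.N,
        "B": order.B,
        "cross": order.cross,
        "standardization": {
            "offset": clf.transform.offset.tolist(),
            "scale": clf.transform.scale.tolist(),
            "degenerate": clf.transform.degenerate.astype(int).tolist(),
        },
        "usable_blocks": list(clf.usable_blocks),
        "unknown_threshold": clf.unknown_threshold,
        "dictionary": [
            [m.nu, list(m.lags), list(m.powers)] for m in order.monomials
        ],
        "classes": [],
        "provenance": {
            "seed": seed,
            "train_counts": {c.label: c.n_train for c in clf.classes},
        },
    }
    for cm in clf.classes:
        m = cm.model
        act_set = m.active.tolist()
        rows, cols = np.nonzero(m.omega)
        payload["classes"].append(
            {
                "label": cm.label,
                "monomial_means": m.monomial_means.tolist(),
                "variances": m.variances.tolist(),
                "degenerate": m.degenerate.astype(int).tolist(),
                "active": act_set,
                "omega": [
                    [int(a), int(b), float(m.omega[a, b])]
                    for a, b in zip(rows, cols)
                ],
                "var_tol": m.var_tol,
                "n_train": m.n_train,
                "densities": {
                    str(nu): {
                        "samples": d.samples.tolist(),
                        "h": d.h,
                        "kernel": d.kernel,
                        "floor": d.floor,
                    }
                    for nu, d in cm.densities.items()
                },
            }
        )
    return payload


def _content_hash(payload: dict) -> str:
    body = {k: v for k, v in payload.items() if k != "content_hash"}
    return hashlib.sha256(
        json.dumps(body, sort_keys=True).encode("utf-8")
    ).hexdigest()


def save_model(clf: DiagnosticClassifier, path, seed=None) -> None:
    """Serialize a trained classifier to a versioned JSON model file."""
    payload = _model_payload(clf, seed=seed)
    payload["content_hash"] = _content_hash(payload)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> DiagnosticClassifier:
    """Load a model file; classification after reload is bit-identical.

    Raises :class:`SchemaVersionError` on a version mismatch and
    :class:`ParseError` on truncated or corrupted documents (the stored
    content hash is re-verified).
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: cannot parse model file: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r}, this package reads "
            f"{SCHEMA_VERSION}"
        )
    if payload.get("content_hash") != _content_hash(payload):
        raise ParseError(f"{path}: content hash mismatch (corrupted file?)")

    crit = payload["criterion"]
    criterion = Criterion(
        kind=crit["kind"], order=crit["order"], degree_bound=crit["degree_bound"]
    )
    std = payload["standardization"]
    transform = Standardization(
        offset=np.asarray(std["offset"], dtype=float),
        scale=np.asarray(std["scale"], dtype=float),
        degenerate=np.asarray(std["degenerate"], dtype=bool),
    )
    order = build_dictionary(
        payload["I"], N=payload["N"], B=payload["B"], cross=payload["cross"]
    )
    stored = [
        Monomial(nu, tuple(lags), tuple(powers))
        for nu, lags, powers in payload["dictionary"]
    ]
    if list(order.monomials) != stored:
        raise ParseError(f"{path}: stored dictionary inconsistent with (I, N, B)")

    classes = []
    n = order.size
    for entry in payload["classes"]:
        omega = np.zeros((n, n))
        for a, b, v in entry["omega"]:
            omega[a, b] = v
        model = CanonicalModel(
            order=order,
            monomial_means=np.asarray(entry["monomial_means"], dtype=float),
            variances=np.asarray(entry["variances"], dtype=float),
            omega=omega,
            degenerate=np.asarray(entry["degenerate"], dtype=bool),
            active=np.asarray(entry["active"], dtype=int),
            decision_indices=_decision_indices(
                order, np.asarray(entry["degenerate"], dtype=bool)
            ),
            n_train=entry["n_train"],
            var_tol=entry["var_tol"],
        )
        densities = {
            int(nu): KernelDensity(
                samples=np.asarray(d["samples"], dtype=float),
                h=d["h"],
                kernel=d["kernel"],
                floor=d["floor"],
            )
            for nu, d in entry["densities"].items()
        }
        classes.append(
            ClassModel(
                label=entry["label"],
                model=model,
                densities=densities,
                n_train=entry["n_train"],
            )
        )
    return DiagnosticClassifier(
        criterion=criterion,
        transform=transform,
        classes=classes,
        usable_blocks=tuple(payload["usable_blocks"]),
        unknown_threshold=payload["unknown_threshold"],
    )
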