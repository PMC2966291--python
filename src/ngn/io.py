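"""Dataset readers/writers and the versioned model archive.

Formats: SMILES line files (``.smi``: one molecule per line, optional
whitespace-separated identifier), dataset CSV (columns ``molecule`` and
``target`` and/or ``label``, optionally ``activity`` thresholded on read),
and a JSON model archive holding grammar, configuration and every weight
layer so that the accumulated training can be reloaded byte-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TrainingConfig
from .errors import DataError
from .grammar import load_grammar
from .metrics import NEG, POS, label_by_threshold
from .network import WeightLayer, WeightLayerLibrary, library_layout

MODEL_FORMAT_VERSION = 1


@dataclass
class DatasetRecord:
    id: str
    molecule: str
    target: float | None = None
    label: str | None = None

    def __post_init__(self):
        if not self.molecule:
            raise DataError("empty molecule string")
        if self.target is None and self.label is None:
            raise DataError(f"record {self.id!r}: neither target nor label present")


def read_smi(path) -> list[DatasetRecord]:
    """SMILES line format: first field is the molecule, optional second the
    identifier (auto-numbered from 1 otherwise); blank and ``#`` lines skip."""
    records: list[DatasetRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            mol = fields[0]
            ident = fields[1] if len(fields) > 1 else str(len(records) + 1)
            if not mol:
                raise DataError(f"{path}:{line_no}: blank molecule field")
            records.append(DatasetRecord(id=ident, molecule=mol, target=0.0))
    if not records:
        raise DataError(f"{path}: no molecules found")
    for r in records:
        r.target = None  # .smi carries structures only
        r.label = None
    return records


def write_smi(path, records: list[DatasetRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.molecule} {r.id}\n")


_LABEL_ALIASES = {"pos": POS, "neg": NEG, "1": POS, "0": NEG,
                  "true": POS, "false": NEG}


def read_dataset_csv(path, *, theta: float | None = None,
                     positive_above: bool = True) -> list[DatasetRecord]:
    """Typed dataset records from CSV.

    Requires a ``molecule`` column and at least one of ``target``/``label``
    (or ``activity`` together with ``theta``, which derives labels by
    threshold).  Labels parse case-insensitively from pos/neg/1/0.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    if "molecule" not in cols:
        raise DataError(f"{path}: missing required column 'molecule'")
    has_target = "target" in cols
    has_label = "label" in cols
    has_activity = "activity" in cols
    if not (has_target or has_label or (has_activity and theta is not None)):
        raise DataError(
            f"{path}: need a 'target' or 'label' column "
            "(or 'activity' plus a theta threshold)"
        )
    derived_labels = None
    if has_activity and theta is not None and not has_label:
        acts = []
        for i, v in enumerate(df[cols["activity"]]):
            try:
                acts.append(float(v))
            except ValueError as exc:
                raise DataError(f"{path} row {i + 2}: bad activity {v!r}") from exc
        derived_labels = label_by_threshold(acts, theta, positive_above=positive_above)

    records = []
    for i, row in df.iterrows():
        ident = str(row[cols["id"]]) if "id" in cols and str(row[cols["id"]]) else str(i + 1)
        target = None
        label = None
        if has_target and str(row[cols["target"]]).strip():
            try:
                target = float(row[cols["target"]])
            except ValueError as exc:
                raise DataError(
                    f"{path} row {i + 2}: unparseable target {row[cols['target']]!r}"
                ) from exc
        if has_label and str(row[cols["label"]]).strip():
            raw = str(row[cols["label"]]).strip().lower()
            if raw not in _LABEL_ALIASES:
                raise DataError(f"{path} row {i + 2}: unknown label {raw!r}")
            label = _LABEL_ALIASES[raw]
        elif derived_labels is not None:
            label = derived_labels[i]
        records.append(DatasetRecord(id=ident, molecule=str(row[cols["molecule"]]),
                                     target=target, label=label))
    return records


def write_dataset_csv(path, records: list[DatasetRecord]) -> None:
    rows = [
        {"id": r.id, "molecule": r.molecule,
         "target": "" if r.target is None else r.target,
         "label": "" if r.label is None else r.label}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# model archive


def save_model(path, lib: WeightLayerLibrary) -> None:
    """Versioned JSON archive: grammar text, config, and all weight layers
    (weights, biases and momentum buffers, full precision)."""
    import dataclasses

    doc = {
        "format": "ngn-model",
        "version": MODEL_FORMAT_VERSION,
        "grammar_name": lib.grammar.name,
        "grammar_text": lib.grammar.serialize(),
        "config": dataclasses.asdict(lib.config),
        "layers": {
            json.dumps(list(k)): {
                "w": layer.w.tolist(),
                "b": layer.b.tolist(),
                "dw_prev": layer.dw_prev.tolist(),
                "db_prev": layer.db_prev.tolist(),
            }
            for k, layer in lib.layers.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> WeightLayerLibrary:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "ngn-model":
        raise DataError(f"{path}: not an ngn model archive")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise DataError(f"{path}: unsupported archive version {doc.get('version')}")
    cfg_kw = dict(doc["config"])
    if isinstance(cfg_kw.get("hidden_size"), dict):
        cfg_kw["hidden_size"] = {k: int(v) for k, v in cfg_kw["hidden_size"].items()}
    cfg = TrainingConfig(**cfg_kw)
    g = load_grammar(doc["grammar_text"], name=doc["grammar_name"])
    specs = library_layout(g, cfg)
    layers = {}
    for k_json, payload in doc["layers"].items():
        key = tuple(json.loads(k_json))
        layer = WeightLayer(np.array(payload["w"], dtype=float),
                            np.array(payload["b"], dtype=float))
        layer.dw_prev = np.array(payload["dw_prev"], dtype=float)
        layer.db_prev = np.array(payload["db_prev"], dtype=float)
        layers[key] = layer
    lib = WeightLayerLibrary(g, cfg, layers, specs)
    missing = set(lib.key_order) - set(layers)
    if missing:
        raise DataError(f"{path}: archive missing layers for keys {sorted(missing)}")
    return lib
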