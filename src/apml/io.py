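"""Serialization: CTM tables (TSV), datasets (TSV manifests), models
(JSON), PBM (P1) images, and run manifests.

Every format round-trips losslessly and serializes in a sorted,
diff-stable order; floats are written with shortest-repr precision so
save -> load -> save is byte-identical.  Matrices serialize row-major,
row 0 = earliest time, most-significant-bit first.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ._bits import bits_to_str, str_to_bits
from .classify import CentroidModel, DistanceSpec, PairingPlan
from .complexity import ConditionalCtmTable, CropSpec, CtmTable, PartitionSpec
from .dynamics import LabeledDataset

__all__ = [
    "save_ctm_table",
    "load_ctm_table",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "write_pbm",
    "read_pbm",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# CTM tables


def _parse_crop(desc: str) -> Optional[CropSpec]:
    if not desc or desc == "none":
        return None
    parts = dict(p.split("=") for p in desc.split(";"))
    parse = lambda v: None if v == "-" else tuple(int(x) for x in v.split(":"))
    return CropSpec(condition=parse(parts["cond"]), outcome=parse(parts["out"]))


def save_ctm_table(table: Union[CtmTable, ConditionalCtmTable], path) -> None:
    path = Path(path)
    lines = []
    if isinstance(table, ConditionalCtmTable):
        lines.append("#kind\tconditional")
        lines.append(f"#pair_count\t{table.pair_count}")
        lines.append(f"#fallback_bits\t{table.fallback_bits}")
        lines.append(f"#crop\t{table.crop.describe() if table.crop else 'none'}")
    else:
        lines.append("#kind\tbase")
    for k, v in sorted(table.metadata.items()):
        if k != "crop":
            lines.append(f"#meta\t{k}\t{v}")
    lines.append(f"#source\t{table.metadata.get('source', 'unknown')}")
    if isinstance(table, ConditionalCtmTable):
        for (cond, out) in sorted(table.entries):
            lines.append(f"{cond}\t{out}\t{table.entries[(cond, out)]!r}")
    else:
        for key in sorted(table.entries):
            lines.append(f"{key}\t{table.entries[key]!r}")
    path.write_text("\n".join(lines) + "\n")


def load_ctm_table(path) -> Union[CtmTable, ConditionalCtmTable]:
    path = Path(path)
    kind = None
    pair_count = None
    crop = None
    metadata: dict = {}
    entries: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if line.startswith("#"):
            tag = cells[0][1:]
            if tag == "kind":
                kind = cells[1]
            elif tag == "pair_count":
                pair_count = int(cells[1])
            elif tag == "fallback_bits":
                pass  # derived from pair_count on load
            elif tag == "crop":
                metadata["crop"] = cells[1]
                crop = _parse_crop(cells[1])
            elif tag == "meta":
                val = cells[2]
                metadata[cells[1]] = int(val) if val.lstrip("-").isdigit() else val
            elif tag == "source":
                metadata["source"] = cells[1]
            else:
                raise ValueError(f"{path}:{lineno}: unknown header {tag!r}")
            continue
        if kind == "conditional":
            if len(cells) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            entries[(cells[0], cells[1])] = float(cells[2])
        elif kind == "base":
            if len(cells) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            entries[cells[0]] = float(cells[1])
        else:
            raise ValueError(f"{path}:{lineno}: table rows before #kind header")
    if kind == "conditional":
        if pair_count is None:
            raise ValueError(f"{path}: missing #pair_count header")
        return ConditionalCtmTable(entries, pair_count, crop=crop, metadata=metadata)
    if kind == "base":
        return CtmTable(entries, metadata=metadata)
    raise ValueError(f"{path}: missing #kind header")


# ---------------------------------------------------------------------------
# datasets


def save_dataset(splits: dict, path) -> None:
    """Serialize a {split: LabeledDataset} bundle into one TSV with
    inline row-major bit strings."""
    path = Path(path)
    lines = []
    for split in sorted(splits):
        ds = splits[split]
        lines.append(f"#manifest\t{split}\t{json.dumps(ds.manifest, sort_keys=True)}")
    lines.append("#columns\tid\tsplit\tlabel\tshape\tbits")
    counter = 0
    for split in sorted(splits):
        ds = splits[split]
        for x, lab in zip(ds.samples, ds.labels):
            arr = np.asarray(x)
            shape = "x".join(map(str, arr.shape))
            lines.append(f"{counter}\t{split}\t{lab}\t{shape}\t{bits_to_str(arr)}")
            counter += 1
    path.write_text("\n".join(lines) + "\n")


def load_dataset(path) -> dict:
    path = Path(path)
    manifests: dict = {}
    rows: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if line.startswith("#manifest"):
            manifests[cells[1]] = json.loads(cells[2])
            continue
        if line.startswith("#"):
            continue
        if len(cells) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns")
        _, split, label, shape, bits = cells
        arr = str_to_bits(bits, tuple(int(d) for d in shape.split("x")))
        rows.setdefault(split, ([], []))
        rows[split][0].append(arr)
        rows[split][1].append(label)
    out = {}
    for split, (samples, labels) in rows.items():
        manifest = manifests.get(split, {})
        labels = _restore_labels(labels, manifest)
        out[split] = LabeledDataset(samples, labels, split, manifest=manifest)
    return out


def _restore_labels(labels, manifest):
    classes = manifest.get("classes")
    if classes and all(isinstance(c, int) for c in classes):
        return [int(l) for l in labels]
    return labels


# ---------------------------------------------------------------------------
# models


def save_model(model: CentroidModel, path) -> None:
    path = Path(path)
    spec = model.distance
    payload = {
        "classes": [
            {"label": lab,
             "centroid_bits": c if isinstance(c, str) else bits_to_str(c),
             "shape": None if isinstance(c, str) else list(np.asarray(c).shape)}
            for lab, c in model.items()],
        "distance": {
            "kind": spec.kind,
            "partition": list(spec.partition.block_shape) if spec.partition else None,
            "centroid_partition": (list(spec.centroid_partition.block_shape)
                                   if spec.centroid_partition else None),
            "plan": [spec.plan.strategy, spec.plan.cost_model],
        },
        "provenance": model.provenance,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_model(path, cond_table=None, base_table=None) -> CentroidModel:
    """Rebuild a model from JSON; the CTM tables travel separately (pass
    the table the distance spec needs)."""
    payload = json.loads(Path(path).read_text())
    d = payload["distance"]
    spec = DistanceSpec(
        kind=d["kind"],
        partition=PartitionSpec(tuple(d["partition"])) if d["partition"] else None,
        centroid_partition=(PartitionSpec(tuple(d["centroid_partition"]))
                            if d["centroid_partition"] else None),
        cond_table=cond_table,
        base_table=base_table,
        plan=PairingPlan(strategy=d["plan"][0], cost_model=d["plan"][1]),
    )
    classes, centroids = [], []
    for entry in payload["classes"]:
        classes.append(entry["label"])
        if entry["shape"] is None:
            centroids.append(entry["centroid_bits"])
        else:
            centroids.append(str_to_bits(entry["centroid_bits"], tuple(entry["shape"])))
    return CentroidModel(classes, centroids, spec, provenance=payload.get("provenance", {}))


# ---------------------------------------------------------------------------
# PBM (P1) images


def write_pbm(arr, path) -> None:
    arr = np.asarray(arr, dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError("PBM images are 2-D")
    rows = "\n".join(" ".join(map(str, row)) for row in arr.tolist())
    Path(path).write_text(f"P1\n{arr.shape[1]} {arr.shape[0]}\n{rows}\n")


def read_pbm(path) -> np.ndarray:
    tokens = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path}: not a plain PBM (P1) file")
    w, h = int(tokens[1]), int(tokens[2])
    bits = np.array(tokens[3:3 + w * h], dtype=np.uint8)
    if bits.size != w * h:
        raise ValueError(f"{path}: expected {w * h} pixels, found {bits.size}")
    return bits.reshape(h, w)


# ---------------------------------------------------------------------------
# run manifests


class RunManifest:
    """Reproducibility record of a CLI run: command, config, top-level
    seed and named substream seeds, table hashes and output paths."""

    def __init__(self, command: str, config: dict, seed: Optional[int] = None):
        self.payload = {
            "command": command,
            "config": config,
            "seed": seed,
            "substreams": {},
            "tables": {},
            "outputs": [],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def note_substream(self, name: str) -> None:
        self.payload["substreams"][name] = f"crc32({name!r}) child of seed"

    def note_table(self, name: str, table) -> None:
        self.payload["tables"][name] = {
            "source": table.metadata.get("source", "unknown"),
            "entries": len(table.entries),
        }

    def note_output(self, path) -> None:
        self.payload["outputs"].append(str(path))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=1, sort_keys=True) + "\n")
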