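"""Readers, writers and reporting glue.

Images and masks travel as 8-bit PNG/TIFF; graphs round-trip either
through a pair of plain-text tab-separated tables (node table: id,
centroid, features, target; edge table: s, t, u_x, u_y) or through a
compact ``.npz`` container.  Floats in the text format are written with
17 significant digits, so both routes are lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .graph import SuperpixelGraph

_FMT = "%.17g"


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as a grayscale array in [0, 1] (value / 255)."""
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr.astype(np.float64) / 255.0


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] grayscale array as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a binary mask stored with 0/255 values; returns {0, 1} int array."""
    return (read_image(path) >= 0.5).astype(np.int64)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


# -- graph serialisation ---------------------------------------------------

def save_graph_text(graph: SuperpixelGraph, prefix) -> None:
    """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``."""
    prefix = Path(prefix)
    n_feat = graph.features.shape[1]
    header = ["id", "row", "col"] + [f"f{i}" for i in range(n_feat)]
    has_t = graph.targets is not None
    if has_t:
        header.append("target")
    with open(prefix.with_suffix(".nodes.tsv"), "w") as fh:
        fh.write("\t".join(header) + "\n")
        fh.write(f"# coord_scale\t{_FMT % graph.coord_scale}\n")
        for k in range(graph.node_count):
            row = [str(k), _FMT % graph.centroids[k, 0], _FMT % graph.centroids[k, 1]]
            row += [_FMT % x for x in graph.features[k]]
            if has_t:
                row.append(_FMT % graph.targets[k])
            fh.write("\t".join(row) + "\n")
    with open(prefix.with_suffix(".edges.tsv"), "w") as fh:
        fh.write("s\tt\tu_x\tu_y\n")
        for s, t, (ux, uy) in zip(graph.edge_src, graph.edge_dst, graph.pseudo):
            fh.write(f"{s}\t{t}\t{_FMT % ux}\t{_FMT % uy}\n")


def load_graph_text(prefix) -> SuperpixelGraph:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".nodes.tsv")) as fh:
        header = fh.readline().strip().split("\t")
        scale_line = fh.readline().strip().split("\t")
        coord_scale = float(scale_line[1])
        rows = [line.strip().split("\t") for line in fh if line.strip()]
    has_t = header[-1] == "target"
    n_feat = len(header) - 3 - (1 if has_t else 0)
    centroids = np.array([[float(r[1]), float(r[2])] for r in rows])
    features = np.array([[float(x) for x in r[3:3 + n_feat]] for r in rows])
    targets = np.array([float(r[-1]) for r in rows]) if has_t else None
    edata = np.loadtxt(prefix.with_suffix(".edges.tsv"), skiprows=1, ndmin=2)
    return SuperpixelGraph(
        node_count=len(rows), features=features,
        edge_src=edata[:, 0].astype(np.int64), edge_dst=edata[:, 1].astype(np.int64),
        pseudo=edata[:, 2:4], centroids=centroids, targets=targets,
        coord_scale=coord_scale)


def save_graph_npz(graph: SuperpixelGraph, path) -> None:
    data = dict(
        features=graph.features, edge_src=graph.edge_src, edge_dst=graph.edge_dst,
        pseudo=graph.pseudo, centroids=graph.centroids,
        coord_scale=np.array(graph.coord_scale))
    if graph.targets is not None:
        data["targets"] = graph.targets
    if graph.labels is not None:
        data["labels"] = graph.labels
    np.savez_compressed(path, **data)


def load_graph_npz(path) -> SuperpixelGraph:
    with np.load(path) as z:
        return SuperpixelGraph(
            node_count=z["features"].shape[0], features=z["features"],
            edge_src=z["edge_src"], edge_dst=z["edge_dst"], pseudo=z["pseudo"],
            centroids=z["centroids"],
            targets=z["targets"] if "targets" in z else None,
            labels=z["labels"] if "labels" in z else None,
            coord_scale=float(z["coord_scale"]))


# -- reports and manifests -------------------------------------------------

def write_report(results: Dict[str, Dict[str, float]], path,
                 counts: Optional[Dict[str, int]] = None) -> None:
    """CSV accuracy table: rows = splits, columns = models/rules, cells in percent.

    ``results[split][rule]`` is a fraction in [0, 1]; an optional
    ``counts[split]`` adds a final ``#D`` cardinality column.
    """
    rules: list = []
    for per_split in results.values():
        for rule in per_split:
            if rule not in rules:
                rules.append(rule)
    lines = ["split," + ",".join(rules) + (",#D" if counts else "")]
    for split, per_split in results.items():
        cells = [f"{100.0 * per_split[r]:.2f}%" if r in per_split else "" for r in rules]
        if counts:
            cells.append(str(counts.get(split, "")))
        lines.append(f"{split}," + ",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def array_fingerprint(arr: np.ndarray) -> str:
    """Content hash of an array (dtype/shape-sensitive)."""
    h = hashlib.sha256()
    arr = np.ascontiguousarray(arr)
    h.update(str(arr.dtype).encode())
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def write_manifest(path, config: dict, seeds: dict,
                   fingerprints: Optional[dict] = None,
                   artifacts: Optional[dict] = None) -> None:
    """Experiment manifest: config snapshot, seeds, data hashes, artifact paths."""
    payload = {"config": config, "seeds": seeds,
               "fingerprints": fingerprints or {}, "artifacts": artifacts or {}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
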