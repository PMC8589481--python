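"""Plain-text readers/writers for triples, interactions, documents and vectors.

All formats are tab-separated text so artifacts stay inspectable:

* triples:       ``head<TAB>relation<TAB>tail``
* interactions:  ``user<TAB>item<TAB>label`` with label in {0,1}
* documents:     ``entity_id<TAB>text``
* vectors:       ``id<TAB>v1,v2,...`` plus an optional JSON sidecar header
* images:        one whitespace-separated numeric grid per file (or PNG)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .kg_embedding import Triple


def write_triples(path, triples) -> None:
    with open(path, "w") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def read_triples(path) -> list[Triple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            h, r, t = line.split("\t")
            out.append(Triple(h, r, t))
    return out


def write_interactions(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.user}\t{rec.item}\t{rec.label}\n")


def read_interactions(path):
    from .multitask import InteractionRecord

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, i, y = line.split("\t")
            out.append(InteractionRecord(u, i, int(y)))
    return out


def write_documents(path, documents: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for eid, text in documents.items():
            fh.write(f"{eid}\t{text}\n")


def read_documents(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            eid, text = line.split("\t", 1)
            out[eid] = text
    return out


def write_vectors(path, vectors: dict[str, np.ndarray], header: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, vec in vectors.items():
            fh.write(key + "\t" + ",".join(f"{v:.10g}" for v in np.asarray(vec).ravel()) + "\n")
    if header is not None:
        Path(str(path) + ".json").write_text(json.dumps(header, indent=2))


def read_vectors(path) -> dict[str, np.ndarray]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, vals = line.split("\t")
            out[key] = np.array([float(v) for v in vals.split(",")])
    return out


def write_image(path, image: np.ndarray) -> None:
    path = str(path)
    if path.endswith(".png"):
        from PIL import Image

        Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8)).save(path)
    else:
        np.savetxt(path, image, fmt="%.6g")


def read_image(path) -> np.ndarray:
    path = str(path)
    if path.endswith(".png"):
        from PIL import Image

        return np.asarray(Image.open(path), dtype=np.float64) / 255.0
    return np.loadtxt(path, dtype=np.float64)
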