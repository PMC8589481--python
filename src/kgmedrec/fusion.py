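"""Multimodal entity encoder: structural + textual + visual -> one vector.

Each knowledge-graph entity may carry up to three representations — a
structural embedding, a sentence vector for its symptom text, and an image
feature vector.  They are concatenated (an absent modality is replaced by a
learned per-modality default vector) and passed through a single dense
layer with a nonlinearity, yielding the entity vector used both as the
tail representation of the KG-embedding task and as the entity-side input
of the cross-compression unit.

The dense layer is implemented blockwise — one weight block per modality —
which is algebraically identical to concatenation followed by one dense
matrix and keeps ablations (base / base+text / base+image / full) a pure
matter of which inputs are supplied, with no code-path changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import VocabularyError

__all__ = ["FusionConfig", "MultimodalEntityFeatures", "FusionEncoder", "encode_all"]


@dataclass
class FusionConfig:
    dim_struct: int = 16
    dim_text: int = 16
    dim_image: int = 32
    dim_out: int = 16
    activation: str = "tanh"   # or "linear"
    seed: int = 0


@dataclass
class MultimodalEntityFeatures:
    entity_id: str
    structural: np.ndarray | None = None
    textual: np.ndarray | None = None
    visual: np.ndarray | None = None
    fused: np.ndarray | None = None


class FusionEncoder:
    """Concatenation + one dense layer, with learned missing-modality defaults."""

    def __init__(self, config: FusionConfig | None = None):
        self.config = config or FusionConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        def block(d_in):
            s = np.sqrt(6.0 / (d_in + cfg.dim_out))
            return Tensor.param(rng.uniform(-s, s, (d_in, cfg.dim_out)))

        self.w_struct = block(cfg.dim_struct)
        # text/image blocks start at zero (residual-style): every modality
        # configuration begins functionally identical to the structural-only
        # model, and the extra paths grow only where gradients support them
        self.w_text = Tensor.param(np.zeros((cfg.dim_text, cfg.dim_out)))
        self.w_image = Tensor.param(np.zeros((cfg.dim_image, cfg.dim_out)))
        self.bias = Tensor.param(np.zeros(cfg.dim_out))
        # defaults start at zero: an absent modality initially contributes nothing
        self.default_struct = Tensor.param(np.zeros(cfg.dim_struct))
        self.default_text = Tensor.param(np.zeros(cfg.dim_text))
        self.default_image = Tensor.param(np.zeros(cfg.dim_image))

    def params(self) -> list[Tensor]:
        return [self.w_struct, self.w_text, self.w_image, self.bias,
                self.default_struct, self.default_text, self.default_image]

    def _act(self, y: Tensor) -> Tensor:
        if self.config.activation == "tanh":
            return y.tanh()
        if self.config.activation == "linear":
            return y
        raise ValueError(f"unknown activation {self.config.activation!r}")

    def forward_table(self, struct: Tensor,
                      text: np.ndarray | None, text_mask: np.ndarray | None,
                      image: np.ndarray | None, image_mask: np.ndarray | None,
                      ) -> Tensor:
        """Fuse a whole entity table (differentiable path for joint training).

        `struct` is (n_e, dim_struct); `text`/`image` are constant feature
        matrices with binary masks (1 = modality present for that entity);
        None disables the modality entirely (its default vector is used).
        """
        n_e = struct.shape[0]
        y = struct @ self.w_struct + self.bias

        def modality(mat, mask, default, w):
            if mat is None:
                return Tensor(np.ones((n_e, 1))) * (default @ w)
            mask = np.asarray(mask, dtype=np.float64).reshape(n_e, 1)
            present = Tensor(mask) * (Tensor(mat) @ w)
            missing = Tensor(1.0 - mask) * (default @ w)
            return present + missing

        y = y + modality(text, text_mask, self.default_text, self.w_text)
        y = y + modality(image, image_mask, self.default_image, self.w_image)
        return self._act(y)

    def fuse(self, features: MultimodalEntityFeatures) -> np.ndarray:
        """Fuse one entity's modalities into a single vector."""
        if (features.structural is None and features.textual is None
                and features.visual is None):
            raise ValueError(f"entity {features.entity_id!r}: all modalities absent")
        cfg = self.config
        pairs = [
            (features.structural, self.default_struct.data, self.w_struct.data, cfg.dim_struct),
            (features.textual, self.default_text.data, self.w_text.data, cfg.dim_text),
            (features.visual, self.default_image.data, self.w_image.data, cfg.dim_image),
        ]
        y = self.bias.data.copy()
        for vec, default, w, dim in pairs:
            v = default if vec is None else np.asarray(vec, dtype=np.float64)
            if v.shape != (dim,):
                raise ValueError(f"modality vector has shape {v.shape}, expected ({dim},)")
            y = y + v @ w
        out = np.tanh(y) if cfg.activation == "tanh" else y
        features.fused = out
        return out


def encode_all(entities: list[str], structural: dict[str, np.ndarray],
               text_vectors: dict[str, np.ndarray] | None,
               image_vectors: dict[str, np.ndarray] | None,
               encoder: FusionEncoder) -> dict[str, np.ndarray]:
    """One fused vector per entity; text/image tables may cover a subset."""
    known = set(entities)
    for name, table in (("text", text_vectors), ("image", image_vectors)):
        for eid in (table or {}):
            if eid not in known:
                raise VocabularyError(f"{name} table references unknown entity {eid!r}")
    out = {}
    for eid in entities:
        feats = MultimodalEntityFeatures(
            entity_id=eid,
            structural=structural[eid],
            textual=(text_vectors or {}).get(eid),
            visual=(image_vectors or {}).get(eid),
        )
        out[eid] = encoder.fuse(feats)
    return out
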