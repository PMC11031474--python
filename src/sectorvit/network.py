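"""The sector-split vision transformer.

Heterogeneous inputs — a demographics pair, six radiomic feature vectors and
two MR images — are tokenized per *sector*: each tabular/radiomic sector maps
to a single learned token, each image sector to a grid of patch tokens.  A
learned class token is prepended, the whole sequence runs through a shared
pre-norm transformer encoder, and every sector (plus the class token) gets its
own logistic prediction head.  The total model output is the majority vote of
the nine data-sector calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import (CohortDataset, DEMOGRAPHIC_SECTOR, IMAGE_SECTORS,
                     RADIOMIC_SECTORS, SECTOR_ORDER)

CLASS_TOKEN = "class-token"
HEAD_ORDER = SECTOR_ORDER + (CLASS_TOKEN,)


@dataclass
class SectorSpec:
    name: str
    kind: str               # {tabular, radiomic, image}
    input_length: int       # flattened length of the sector's array
    token_count: int


@dataclass
class ModelConfig:
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 2.0
    patch_size: int = 16
    dropout: float = 0.1
    attention_scope: str = "joint"          # or "sector-restricted"
    vote_members: str = "data-sectors-only"  # or "all-heads"
    image_size: int = 128
    radiomic_length: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.image_size % self.patch_size != 0:
            raise ValueError("patch_size must divide image_size")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.attention_scope not in ("joint", "sector-restricted"):
            raise ValueError(f"unknown attention_scope {self.attention_scope!r}")
        if self.vote_members not in ("data-sectors-only", "all-heads"):
            raise ValueError(f"unknown vote_members {self.vote_members!r}")


def default_sector_specs(config: ModelConfig) -> list[SectorSpec]:
    """The nine data sectors: 1 demographic, 6 radiomic, 2 image."""
    n_patches = (config.image_size // config.patch_size) ** 2
    specs = [SectorSpec(DEMOGRAPHIC_SECTOR, "tabular", 2, 1)]
    specs += [SectorSpec(name, "radiomic", config.radiomic_length, 1)
              for name in RADIOMIC_SECTORS]
    specs += [SectorSpec(name, "image", config.image_size ** 2, n_patches)
              for name in IMAGE_SECTORS]
    return specs


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, S, S) images -> (B, (S/p)^2, p^2) row-major patch vectors."""
    b, s, _ = images.shape
    g = s // patch_size
    x = images.reshape(b, g, patch_size, g, patch_size)
    return x.transpose(0, 1, 3, 2, 4).reshape(b, g * g, patch_size * patch_size)


def cohort_inputs(cohort: CohortDataset) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack a cohort's samples into per-sector arrays (plus labels)."""
    inputs: dict[str, np.ndarray] = {
        DEMOGRAPHIC_SECTOR: np.stack([s.demographics for s in cohort.samples]),
        "CE-T1WI": np.stack([s.image_ce_t1 for s in cohort.samples]),
        "T2WI": np.stack([s.image_t2 for s in cohort.samples]),
    }
    for name in RADIOMIC_SECTORS:
        inputs[name] = np.stack([s.radiomics[name] for s in cohort.samples])
    return inputs, cohort.labels


def vote_fusion(calls: Sequence[int], probs: Sequence[float] | None = None) -> int:
    """Majority vote over binary head calls.

    With an odd number of voters the majority is always strict; an even-count
    tie (reachable only when the class-token head joins the vote) is broken by
    whether the mean head probability reaches 0.5.
    """
    calls = np.asarray(calls)
    ones = int(calls.sum())
    zeros = len(calls) - ones
    if ones != zeros:
        return int(ones > zeros)
    if probs is None:
        raise ValueError("tie requires probabilities for tie-breaking")
    return int(float(np.mean(probs)) >= 0.5)


class VViTNetwork:
    """Parameters + forward pass of the sector transformer."""

    def __init__(self, config: ModelConfig,
                 specs: Sequence[SectorSpec] | None = None):
        self.config = config
        self.specs = list(specs) if specs is not None else default_sector_specs(config)
        self.head_names = [s.name for s in self.specs] + [CLASS_TOKEN]
        # token layout: class token first, then sectors in spec order
        self.token_slices: dict[str, slice] = {}
        start = 1
        for s in self.specs:
            self.token_slices[s.name] = slice(start, start + s.token_count)
            start += s.token_count
        self.n_tokens = start
        self.params: dict[str, Tensor] = {}
        self._init_params(config.seed)
        self._mask = self._build_mask()

    # -- parameters --------------------------------------------------------

    def _param(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True)

    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        d = self.config.embed_dim

        def normal(*shape):
            return rng.normal(0.0, 0.02, size=shape)

        self._param("cls", normal(1, d))
        for s in self.specs:
            in_len = (self.config.patch_size ** 2 if s.kind == "image"
                      else s.input_length)
            self._param(f"embed/{s.name}/W", normal(in_len, d))
            self._param(f"embed/{s.name}/b", np.zeros(d))
            self._param(f"embed/{s.name}/pos", normal(s.token_count, d))
        for layer in range(self.config.depth):
            pre = f"enc{layer}/"
            self._param(pre + "ln1_g", np.ones(d))
            self._param(pre + "ln1_b", np.zeros(d))
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                self._param(pre + nm, normal(d, d))
            for nm in ("bq", "bk", "bv", "bo"):
                self._param(pre + nm, np.zeros(d))
            self._param(pre + "ln2_g", np.ones(d))
            self._param(pre + "ln2_b", np.zeros(d))
            hidden = int(d * self.config.mlp_ratio)
            self._param(pre + "W1", normal(d, hidden))
            self._param(pre + "b1", np.zeros(hidden))
            self._param(pre + "W2", normal(hidden, d))
            self._param(pre + "b2", np.zeros(d))
        self._param("ln_f_g", np.ones(d))
        self._param("ln_f_b", np.zeros(d))
        for name in self.head_names:
            self._param(f"head/{name}/W", normal(d, 1))
            self._param(f"head/{name}/b", np.zeros(1))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- attention mask ----------------------------------------------------

    def _build_mask(self) -> np.ndarray | None:
        """Additive attention mask for the sector-restricted scope.

        Each data sector's tokens attend only within the sector; the class
        token reads every token but is read by no data token, so permuting one
        sector's content cannot leak into any other sector's head.
        """
        if self.config.attention_scope == "joint":
            return None
        t = self.n_tokens
        allowed = np.zeros((t, t), dtype=bool)
        allowed[0, :] = True  # class token attends everywhere
        for s in self.specs:
            sl = self.token_slices[s.name]
            allowed[sl, sl] = True
        mask = np.where(allowed, 0.0, -1e9)
        return mask

    # -- forward -----------------------------------------------------------

    def _embed(self, inputs: Mapping[str, np.ndarray]) -> Tensor:
        cfg = self.config
        b = next(iter(inputs.values())).shape[0]
        toks: list[Tensor] = []
        # class token broadcast across the batch
        cls = self.params["cls"].reshape(1, 1, cfg.embed_dim) + Tensor(np.zeros((b, 1, 1)))
        toks.append(cls)
        for s in self.specs:
            x = np.asarray(inputs[s.name], dtype=np.float64)
            if s.kind == "image":
                x = patchify(x, cfg.patch_size)          # (B, P, p^2)
            else:
                x = x.reshape(b, 1, s.input_length)      # (B, 1, len)
            proj = (Tensor(x) @ self.params[f"embed/{s.name}/W"]
                    + self.params[f"embed/{s.name}/b"]
                    + self.params[f"embed/{s.name}/pos"])
            toks.append(proj)
        return ad.concatenate(toks, axis=1)              # (B, T, D)

    def _dropout(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    def forward(self, inputs: Mapping[str, np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Head probabilities, shape (B, 10), columns in ``head_names`` order."""
        cfg = self.config
        d, h = cfg.embed_dim, cfg.n_heads
        dh = d // h
        scale = dh ** -0.5
        x = self._embed(inputs)
        b, t = x.shape[0], x.shape[1]
        mask = None if self._mask is None else Tensor(self._mask)
        for layer in range(cfg.depth):
            p = self.params
            pre = f"enc{layer}/"
            xn = ad.layer_norm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])

            def split_heads(z: Tensor) -> Tensor:
                return z.reshape(b, t, h, dh).transpose((0, 2, 1, 3))

            q = split_heads(xn @ p[pre + "Wq"] + p[pre + "bq"])
            k = split_heads(xn @ p[pre + "Wk"] + p[pre + "bk"])
            v = split_heads(xn @ p[pre + "Wv"] + p[pre + "bv"])
            scores = (q @ k.transpose((0, 1, 3, 2))) * scale
            if mask is not None:
                scores = scores + mask
            att = ad.softmax(scores, axis=-1)
            ctx = (att @ v).transpose((0, 2, 1, 3)).reshape(b, t, d)
            x = x + self._dropout(ctx @ p[pre + "Wo"] + p[pre + "bo"], training, rng)
            xn2 = ad.layer_norm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            hdn = ad.gelu(xn2 @ p[pre + "W1"] + p[pre + "b1"])
            x = x + self._dropout(hdn @ p[pre + "W2"] + p[pre + "b2"], training, rng)
        x = ad.layer_norm(x, self.params["ln_f_g"], self.params["ln_f_b"])

        probs: list[Tensor] = []
        for s in self.specs:
            pooled = x[:, self.token_slices[s.name], :].mean(axis=1)
            logit = pooled @ self.params[f"head/{s.name}/W"] + self.params[f"head/{s.name}/b"]
            probs.append(ad.sigmoid(logit))
        cls_logit = x[:, 0, :] @ self.params[f"head/{CLASS_TOKEN}/W"] \
            + self.params[f"head/{CLASS_TOKEN}/b"]
        probs.append(ad.sigmoid(cls_logit))
        out = ad.concatenate(probs, axis=1)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite head probabilities "
                                     f"(min={np.nanmin(out.data)}, max={np.nanmax(out.data)})")
        return out

    # -- inference ---------------------------------------------------------

    def predict_proba(self, inputs: Mapping[str, np.ndarray],
                      batch_size: int = 64) -> np.ndarray:
        """Deterministic head probabilities, batched; (N, n_heads)."""
        n = next(iter(inputs.values())).shape[0]
        if n == 0:
            return np.zeros((0, len(self.head_names)))
        chunks = []
        for start in range(0, n, batch_size):
            batch = {k: v[start:start + batch_size] for k, v in inputs.items()}
            chunks.append(self.forward(batch, training=False).data)
        return np.concatenate(chunks, axis=0)

    def _vote_columns(self) -> list[str]:
        if self.config.vote_members == "all-heads":
            return list(self.head_names)
        return [s.name for s in self.specs]

    def predict_table(self, cohort: CohortDataset, batch_size: int = 64) -> pd.DataFrame:
        """Per-sample sector predictions.

        Columns: sample/patient ids, label, ``prob:<head>`` / ``call:<head>``
        per head, and the voted ``total_call`` with ``total_prob`` (mean of the
        voting heads' probabilities).
        """
        cols: dict[str, object] = {
            "sample_id": [s.slice_id for s in cohort.samples],
            "patient_id": [s.patient_id for s in cohort.samples],
            "label": cohort.labels,
        }
        if len(cohort) == 0:
            for name in self.head_names:
                cols[f"prob:{name}"] = []
                cols[f"call:{name}"] = []
            cols["total_prob"], cols["total_call"] = [], []
            return pd.DataFrame(cols)
        inputs, _ = cohort_inputs(cohort)
        probs = self.predict_proba(inputs, batch_size=batch_size)
        calls = (probs >= 0.5).astype(int)
        for j, name in enumerate(self.head_names):
            cols[f"prob:{name}"] = probs[:, j]
            cols[f"call:{name}"] = calls[:, j]
        voters = [self.head_names.index(nm) for nm in self._vote_columns()]
        vote_probs = probs[:, voters]
        vote_calls = calls[:, voters]
        cols["total_prob"] = vote_probs.mean(axis=1)
        cols["total_call"] = np.array([
            vote_fusion(vote_calls[i], vote_probs[i]) for i in range(len(cohort))
        ])
        return pd.DataFrame(cols)

    # -- serialization -----------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file parameter archive with a JSON config sidecar."""
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "VViTNetwork":
        with open(str(path) + ".json") as fh:
            config = ModelConfig(**json.load(fh))
        net = cls(config)
        path = path if str(path).endswith(".npz") else str(path) + ".npz"
        with np.load(path) as archive:
            for key in net.params:
                net.params[key] = Tensor(archive[key], requires_grad=True)
        return net
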