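"""Stacked per-layer sequence labelers.

L linear-chain CRFs are trained bottom-up: layer 1 sees word and stem
features in a window of 5 (offsets -2..+2), layer k > 1 additionally sees
the layer-1..k-1 tags at the same offsets — gold tags during training
(teacher forcing), predicted tags at test time.  Decoding proceeds layer by
layer with deterministic BIESO repair after each layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._crf import ChainCRF
from .hier_tagging import LayeredTags, repair_bieso
from .text_preproc import Token, stem as _stem

WINDOW_OFFSETS = (-2, -1, 0, 1, 2)
_BOS, _EOS = "<S>", "</S>"

FEATURE_TEMPLATE_VERSION = "w5-word-stem-labels-v1"


def _surface_and_stem(tok) -> tuple[str, str]:
    if isinstance(tok, Token):
        return tok.surface, tok.stem or _stem(tok.surface)
    s = str(tok)
    return s, _stem(s)


def featurize(tokens, lower_layer_labels: list[list[str]], k: int) -> list[list[str]]:
    """Window-5 feature vectors for layer *k*.

    ``lower_layer_labels`` must hold the complete tag sequences of layers
    1..k-1 (k-1 sequences).
    """
    n = len(tokens)
    if len(lower_layer_labels) != k - 1:
        raise ValueError(f"layer {k} needs {k - 1} lower label sequences, "
                         f"got {len(lower_layer_labels)}")
    for layer in lower_layer_labels:
        if len(layer) != n:
            raise ValueError("label sequence length does not match tokens")
    pairs = [_surface_and_stem(t) for t in tokens]

    def at(seq, i, default):
        return seq[i] if 0 <= i < n else default

    vectors: list[list[str]] = []
    for i in range(n):
        feats = ["bias"]
        for d in WINDOW_OFFSETS:
            j = i + d
            boundary = _BOS if j < 0 else _EOS
            surface = at([p[0] for p in pairs], j, boundary)
            stemmed = at([p[1] for p in pairs], j, boundary)
            feats.append(f"w[{d}]={surface}")
            feats.append(f"s[{d}]={stemmed}")
            for m, layer in enumerate(lower_layer_labels, start=1):
                feats.append(f"y{m}[{d}]={at(layer, j, boundary)}")
        vectors.append(feats)
    return vectors


@dataclass
class HierModel:
    L: int
    models: list[ChainCRF]
    template_version: str = FEATURE_TEMPLATE_VERSION
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "L": self.L,
            "template_version": self.template_version,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        for k, model in enumerate(self.models, start=1):
            model.save(directory / f"layer_{k}.json")

    @classmethod
    def load(cls, directory) -> "HierModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        models = [
            ChainCRF.load(directory / f"layer_{k}.json")
            for k in range(1, meta["L"] + 1)
        ]
        return cls(meta["L"], models, meta["template_version"], meta["seed"],
                   meta.get("hyperparams", {}))


def train_hier(
    instances: list[tuple[list, LayeredTags]],
    L: int | None = None,
    c2: float = 1.0,
    max_iter: int = 100,
    seed: int = 0,
) -> HierModel:
    """Train the stack of L labelers with gold lower-layer tags as features."""
    if not instances:
        raise ValueError("empty training corpus")
    if L is None:
        L = max(tags.L for _, tags in instances)
    padded = [(tokens, tags.padded(L)) for tokens, tags in instances]
    models: list[ChainCRF] = []
    for k in range(1, L + 1):
        X = [
            featurize(tokens, [tags.layers[m] for m in range(k - 1)], k)
            for tokens, tags in padded
        ]
        y = [tags.layers[k - 1] for _, tags in padded]
        crf = ChainCRF(c2=c2, max_iter=max_iter)
        crf.fit(X, y)
        models.append(crf)
    return HierModel(L, models, seed=seed,
                     hyperparams={"c2": c2, "max_iter": max_iter})


def predict_hier(tokens, model: HierModel) -> LayeredTags:
    """Decode layers 1..L, each consuming the previously predicted layers."""
    if not tokens:
        return LayeredTags([[] for _ in range(model.L)])
    lower: list[list[str]] = []
    for k in range(1, model.L + 1):
        X = [featurize(tokens, lower, k)]
        predicted = model.models[k - 1].predict(X)[0]
        lower.append(repair_bieso(predicted))
    return LayeredTags(lower)
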