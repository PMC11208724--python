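"""The joint model: encoder + predictor + decoder, with checkpointing.

A checkpoint is a flat ``.npz`` of named parameter arrays next to a JSON
manifest recording the architecture (dims, layer counts), the task kind,
the element-vocabulary hash, and the seed the model was built with.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .agrn import Decoder
from .chem import ELEMENTS, MAX_VALENCE
from .encoder import Encoder, Predictor
from .nn import Module

__all__ = ["ModelConfig", "OlbacModel", "vocabulary_hash"]


def vocabulary_hash() -> str:
    payload = json.dumps([ELEMENTS, MAX_VALENCE], sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ModelConfig:
    hidden_dim: int = 64          # embedding width D_h
    encoder_layers: int = 2       # L
    decoder_T: int = 1            # molecule-to-atom rounds
    predictor_hidden: int = 64
    dropout: float = 0.1
    task: str = "regression"      # or "classification"
    with_bonds: bool = True       # build bond heads (loss use is separate)
    seed: int = 0


class OlbacModel(Module):
    """Encoder E, predictor N and decoder G sharing one hidden width.

    The decoder's atom-to-atom depth equals the encoder depth L, mirroring
    the embedding it inverts.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(config.hidden_dim, config.encoder_layers, rng,
                               dropout_p=config.dropout)
        self.predictor = Predictor(config.hidden_dim, config.predictor_hidden, rng)
        self.decoder = Decoder(config.hidden_dim, config.decoder_T,
                               config.encoder_layers, rng,
                               dropout_p=config.dropout,
                               with_bonds=config.with_bonds)

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.state_dict())
        manifest = {
            "format": "olbac-checkpoint-v1",
            "package_version": __version__,
            "vocabulary_hash": vocabulary_hash(),
            "config": asdict(self.config),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "OlbacModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".manifest.json").read_text())
        if manifest.get("vocabulary_hash") != vocabulary_hash():
            raise ValueError("checkpoint was built with a different element vocabulary")
        model = cls(ModelConfig(**manifest["config"]))
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
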