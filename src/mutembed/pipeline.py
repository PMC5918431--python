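"""Orchestration of the four embedding variants.

Variants compose two optional ingredients around the skip-gram core:

* ``basic`` — train on the mutation cohort alone.
* ``PI``    — initialize the embedding lookup matrix from pre-trained
              (literature) word vectors, then train.
* ``R``     — train, then retrofit onto the interaction network.
* ``PI+R``  — both.

``run_pipeline`` reads the inputs, trains, writes the vectors in
word2vec text format, and drops a JSON sidecar recording the seed and a
hash of the full configuration so reruns can be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import io as mio
from .containers import GeneVectorTable, InteractionGraph
from .exceptions import ConfigurationError
from .retrofit import GraphRetrofitter
from .sgns import SkipGramEmbedder

logger = logging.getLogger(__name__)

VARIANTS = ("basic", "PI", "R", "PI+R")


@dataclass
class PipelineConfig:
    """Everything one embedding run depends on."""

    variant: str = "basic"
    profiles_path: str = ""
    pretrained_path: str | None = None
    ppi_path: str | None = None
    out_dir: str = "."
    profiles_format: str = "tsv"
    dim: int = 300
    negatives_per_pair: int = 5
    epochs: int = 5
    lr_initial: float = 0.025
    lr_final: float = 1e-4
    min_count: int = 1
    draws_per_sample: int = 10
    draw_size: int = 10
    retrofit_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if not self.profiles_path:
            raise ConfigurationError("profiles_path is required")
        if "PI" in self.variant.split("+") and not self.pretrained_path:
            raise ConfigurationError(f"variant {self.variant} requires pretrained_path")
        if "R" in self.variant.split("+") and not self.ppi_path:
            raise ConfigurationError(f"variant {self.variant} requires ppi_path")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def embed_variant(
    profiles,
    variant: str,
    pretrained: GeneVectorTable | None = None,
    graph: InteractionGraph | None = None,
    seed: int = 0,
    **embed_params,
) -> GeneVectorTable:
    """In-memory variant runner (the library-level core of the pipeline)."""
    parts = set(variant.split("+"))
    if not parts <= {"basic", "PI", "R"}:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if "PI" in parts and pretrained is None:
        raise ConfigurationError("PI variant needs pre-trained vectors")
    if "R" in parts and graph is None:
        raise ConfigurationError("R variant needs an interaction graph")
    embedder = SkipGramEmbedder(
        pretrained=pretrained if "PI" in parts else None,
        seed=seed,
        **embed_params,
    )
    embedder.fit(profiles)
    table = embedder.embedding_
    if "R" in parts:
        table = GraphRetrofitter(graph=graph).fit(table).transform(table)
    return table


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run one variant end to end, writing artifacts under ``out_dir``.

    Returns a mapping of artifact names to paths.  Rerunning with the
    same config reproduces the vectors bit-identically.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profiles = mio.read_profiles(config.profiles_path, format=config.profiles_format)
    pretrained = (
        mio.read_vectors(config.pretrained_path) if config.pretrained_path else None
    )
    graph = mio.read_edge_list(config.ppi_path) if config.ppi_path else None

    logger.info(
        "variant=%s samples=%d seed=%d", config.variant, len(profiles), config.seed
    )
    logger.info("effective config (defaults included): %s", asdict(config))
    table = embed_variant(
        profiles,
        config.variant,
        pretrained=pretrained,
        graph=graph,
        seed=config.seed,
        dim=config.dim,
        negatives_per_pair=config.negatives_per_pair,
        epochs=config.epochs,
        lr_initial=config.lr_initial,
        lr_final=config.lr_final,
        min_count=config.min_count,
        draws_per_sample=config.draws_per_sample,
        draw_size=config.draw_size,
    )

    vectors_path = out_dir / "vectors.vec"
    mio.write_vectors(table, vectors_path)
    sidecar = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "variant": config.variant,
        "n_vocab": len(table),
        "dim": table.d,
        "config": dataclasses.asdict(config),
    }
    sidecar_path = out_dir / "vectors.meta.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"vectors": str(vectors_path), "sidecar": str(sidecar_path)}
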