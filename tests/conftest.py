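"""Shared fixtures: small scenes and a small trained model.

Expensive fixtures are session-scoped so training happens once; tests that
need isolation build their own models from tiny configs.
"""

from __future__ import annotations

import pytest

import annoloop as al
from annoloop.activeloop import CostModel, OracleConfig, Schedule, simulate_session
from annoloop.model import ModelConfig


TINY_CFG = ModelConfig(depth=3, base_width=4, widths=None, patch_size=64)


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    """Three-level, width-4 network on 64 px patches: fast enough to train
    repeatedly inside the suite."""
    return TINY_CFG


@pytest.fixture(scope="session")
def nuclei_scene() -> al.SyntheticScene:
    """A 256x256 nuclei scene dense enough that every 64 px patch sees structure."""
    return al.generate_scene("nuclei", 256, 256, density=600, seed=11)


def scene_patches(scene: al.SyntheticScene, tile_size: int = 64) -> list[al.Patch]:
    """One fully-annotated patch per tile of the scene."""
    patches = []
    for tile, mask in al.scene_to_tiles(scene, tile_size):
        patches.append(al.Patch(pixels=tile.pixels, tile_id=tile.tile_id,
                                row=0, col=0, mask=mask))
    return patches


@pytest.fixture(scope="session")
def trained_tiny_model(nuclei_scene, tiny_cfg) -> al.SegModel:
    """Pretrained + fine-tuned tiny model on the shared nuclei scene."""
    patches = scene_patches(nuclei_scene)
    model = al.build_model(tiny_cfg, seed=3)
    model = al.pretrain_autoencoder(model, patches, epochs=2, seed=3)
    model = al.finetune(model, patches, epochs=30, seed=3)
    return model


def tiny_session(seed: int, scene_seed: int | None = None, **oracle_kwargs):
    """A complete small session: 256x256 scene, 64 px patches, 3 rounds."""
    scene = al.generate_scene("nuclei", 256, 256, density=600,
                              seed=scene_seed if scene_seed is not None else seed)
    oracle = OracleConfig(cost=CostModel(), **oracle_kwargs)
    schedule = Schedule(patches_per_round=3, rounds=3, epochs_per_round=6,
                        pretrain_epochs=1)
    return simulate_session(scene, model_cfg=TINY_CFG, oracle_cfg=oracle,
                            schedule=schedule, seed=seed)


@pytest.fixture(scope="session")
def tiny_sessions():
    """Three seeded small sessions with the default oracle, shared by the
    efficiency-trend and log-invariant tests."""
    return [tiny_session(seed) for seed in (1, 2, 3)]
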