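"""Genotype preset table, loaded from the versioned YAML config."""

from __future__ import annotations

import functools
from importlib import resources

import yaml

from .models import GenotypePreset

__all__ = ["make_genotype_preset", "supported_genotypes", "sim_globals"]


@functools.lru_cache(maxsize=1)
def _config() -> dict:
    text = resources.files("patchdyn").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def sim_globals() -> dict:
    """Simulator-wide constants (channel lead, eisosome brightness, ...)."""
    return dict(_config()["globals"])


def supported_genotypes() -> list[str]:
    return list(_config()["presets"].keys())


def make_genotype_preset(name: str) -> GenotypePreset:
    """Return the generative parameter set for a genotype label.

    Raises ``KeyError`` with the list of supported labels for unknown names.
    """
    presets = _config()["presets"]
    if name not in presets:
        raise KeyError(
            f"unknown genotype {name!r}; supported: {', '.join(presets)}"
        )
    p = presets[name]
    return GenotypePreset(
        name=name,
        patch_rate=float(p["patch_rate"]),
        lifetime_mean_sd=tuple(p["lifetime"]),
        assembly_mean_sd=tuple(p["assembly"]),
        peak_molecules_mean_sd=tuple(p["peak_molecules"]),
        internalization_prob=float(p["internalization_prob"]),
        query_channel_on_patches_prob=float(p["query_on_patches_prob"]),
        eisosome_amplitude=float(p["eisosome_amplitude"]),
        cytoplasmic_puncta_rate=float(p["puncta_rate"]),
    )
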