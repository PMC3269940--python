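"""Pipeline configuration: rule toggles, filter sets, and tunable weights.

One canonical :class:`PipelineConfig` (the default constructor) reproduces the
full pipeline behaviour; each component can be switched off individually for
ablation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Components that can be individually disabled (ablation harness).
COMPONENTS: tuple[str, ...] = (
    "post_processing",
    "distillation",
    "identifier_extraction",
    "robust_inference",
    "indicator_identifier",
    "indicator_prefix",
    "indicator_previous",
    "indicator_forward",
    "indicator_backward",
    "indicator_majority",
    "intersection_filtering",
    "inference_network",
)

DEFAULT_PREFIX_MAP: dict[str, int] = {
    "h": 9606,   # human
    "m": 10090,  # mouse
    "r": 10116,  # rat
    "d": 7227,   # fruit fly
    "y": 4932,   # budding yeast
    "z": 7955,   # zebrafish
    "x": 8355,   # Xenopus laevis
}

#: Species surface forms that are overwhelmingly false positives in article
#: text, with the taxon they would otherwise hit.
DEFAULT_HIGH_FP: dict[str, int] = {
    "3a": 215167,
    "t7": 10760,
    "cat": 9685,
    "ass": 9793,
    "j1": 1829,
}

#: Experimental-technique phrases whose leading species word must not count as
#: a species mention.
DEFAULT_EXPERIMENT_TERMS: tuple[str, ...] = ("yeast two hybrid", "yeast 2 hybrid")

#: Tokens marking an antibody context; a species mention in their vicinity is
#: a reagent host, not a studied organism.
DEFAULT_ANTIBODY_TOKENS: tuple[str, ...] = (
    "anti-", "antibodies", "polyclonal", "igg", "serum", "monoclonal", "antibody",
)

#: NCBI taxonomy ranks retained in the species lexicon.
DEFAULT_RANK_WHITELIST: tuple[str, ...] = ("species", "no rank", "subspecies", "variants")

#: Disambiguation priority for colliding species names, best first.
DEFAULT_PRIORITY_ORDER: tuple[str, ...] = (
    "species", "no-rank", "subspecies", "variant", "genus",
)


@dataclass
class PipelineConfig:
    # mention recognition / post-processing
    disabled: set[str] = field(default_factory=set)
    # species lexicon
    rank_whitelist: tuple[str, ...] = DEFAULT_RANK_WHITELIST
    priority_order: tuple[str, ...] = DEFAULT_PRIORITY_ORDER
    # species false-positive filtering
    high_fp: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_HIGH_FP))
    experiment_terms: tuple[str, ...] = DEFAULT_EXPERIMENT_TERMS
    antibody_tokens: tuple[str, ...] = DEFAULT_ANTIBODY_TOKENS
    antibody_window: int = 5  # tokens on either side of a species mention
    # assignment
    prefix_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PREFIX_MAP))
    # ranking: convex weight on the exact-entity channel
    lambda_entity: float = 0.7

    def enabled(self, component: str) -> bool:
        if component not in COMPONENTS:
            raise KeyError(f"unknown component: {component!r}")
        return component not in self.disabled

    def without(self, component: str) -> "PipelineConfig":
        """Return a copy with ``component`` disabled (ablation helper)."""
        if component not in COMPONENTS:
            raise KeyError(f"unknown component: {component!r}")
        cfg = PipelineConfig(**{**asdict(self)})
        cfg.disabled = set(self.disabled) | {component}
        cfg.high_fp = dict(self.high_fp)
        cfg.prefix_map = dict(self.prefix_map)
        return cfg

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key!r}")
            if key == "disabled":
                value = set(value)
            elif key in {"rank_whitelist", "priority_order", "experiment_terms",
                         "antibody_tokens"}:
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["disabled"] = sorted(self.disabled)
        for key in ("rank_whitelist", "priority_order", "experiment_terms",
                    "antibody_tokens"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
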