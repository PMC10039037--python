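"""Load and validate the versioned algorithm-coefficient presets.

The legacy algorithms' constants are deliberately kept out of code, in
``data/presets.yaml``, with a citation per preset, because disputed or
device-specific constants should be auditable and overridable without
touching the implementation.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .errors import ParameterError

_REQUIRED_SECTIONS = ("cole_kripke", "oakley", "sadeh", "sazonov", "vanhees")


def load_presets(path=None, overrides: dict | None = None) -> dict:
    """Return the preset dictionary, schema-checked, with optional overrides.

    ``overrides`` is a nested mapping ``{section: {key: value}}`` merged on
    top of the file contents.
    """
    if path is None:
        text = resources.files("actisleep").joinpath("data/presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    presets = yaml.safe_load(text)
    if not isinstance(presets, dict) or "version" not in presets:
        raise ParameterError("preset file must be a mapping with a 'version' key")
    missing = [s for s in _REQUIRED_SECTIONS if s not in presets]
    if missing:
        raise ParameterError(f"preset file missing sections: {missing}")
    for section, values in (overrides or {}).items():
        if section not in presets:
            raise ParameterError(f"override for unknown preset section {section!r}")
        presets[section] = {**presets[section], **values}
    _validate(presets)
    return presets


def _validate(p: dict) -> None:
    for name in ("cole_kripke", "oakley"):
        sec = p[name]
        if not sec.get("weights"):
            raise ParameterError(f"{name}: weights must be non-empty")
        if sec.get("sleep_when") not in ("score_below", "score_at_or_below"):
            raise ParameterError(f"{name}: bad sleep_when")
        if sec.get("epoch_basis_s") not in (30, 60):
            raise ParameterError(f"{name}: epoch_basis_s must be 30 or 60")
    sad = p["sadeh"]
    if not sad["nat_low"] < sad["nat_high"]:
        raise ParameterError("sadeh: nat_low must be < nat_high")
    if sad["window_epochs_each_side"] < 1 or sad["sd_window_epochs"] < 1:
        raise ParameterError("sadeh: window sizes must be >= 1")
    saz = p["sazonov"]
    if not saz["window_weights"]:
        raise ParameterError("sazonov: at least one trailing window required")
    if not 0.0 < saz["probability_threshold"] < 1.0:
        raise ParameterError("sazonov: probability_threshold must be in (0, 1)")
    vh = p["vanhees"]
    if any(vh[k] <= 0 for k in vh):
        raise ParameterError("vanhees: all durations must be positive")
    if vh["min_still_duration_min"] < vh["angle_block_s"] / 60.0:
        raise ParameterError("vanhees: min_still_duration_min shorter than one block")
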