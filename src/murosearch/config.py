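"""Key-value run configuration with the default search settings.

Defaults mirror how the reference *C. difficile* search was configured:
5 ppm precursor tolerance, 20 ppm HCD / 0.5 Da ETD fragment tolerances,
stems AEm/AEmA/AEmG, the five glycoforms, amidation enabled, and a second
wildcard pass (-130 to +210 Da, variable modifications off).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from . import chem

__all__ = ["DEFAULT_CONFIG", "load_config"]

DEFAULT_CONFIG: dict = {
    "stems": ["AEm", "AEmA", "AEmG"],
    "stems_fasta": None,  # optional FASTA path overriding `stems`
    "mzml": None,
    "glycoforms": [
        "MurNAc",
        "GlcN-MurN",
        "GlcN-anhMurNAc",
        "GlcN-MurNAc",
        "GlcNAc-MurNAc",
    ],
    "multimer_glycoforms": [
        "none",
        "MurNAc",
        "GlcN-MurN",
        "GlcN-MurNAc",
        "GlcNAc-MurNAc",
    ],
    "amidation": True,
    "anhydro": True,
    "max_units": 3,
    "precursor_tol_ppm": 5.0,
    "hcd_tol_ppm": 20.0,
    "etd_tol_da": 0.5,
    "xic_tol_ppm": 10.0,
    "wildcard": False,
    "wildcard_range": list(chem.WILDCARD_RANGE),
    "as_configured_masses": False,
    "isd_apex_tol_min": 0.1,
    "isd_min_correlation": 0.95,
    "output_dir": None,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Defaults, optionally updated from a YAML file and keyword overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update(overrides)
    return cfg
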