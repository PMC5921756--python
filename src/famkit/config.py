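"""Key-value configuration.

A YAML file of scalar defaults, merged over built-in values. Schema:

gc: float            background G+C fraction (default 0.28)
sims: int            Monte-Carlo simulation count (default 2000)
seed: int | null     random seed (null = nondeterministic; pipelines
                     should always set one)
tandem_window: int   tandem-cluster gap threshold, bp (default 250000)
gamma: float         substitutions/site/year for dating (default 6.1e-9)
bootstrap: int       bootstrap replicate count (default 1000)
support_threshold: float   sister-pair support cut, percent (default 65)
neutral_tol: float   Ka/Ks neutrality band half-width (default 0.05)
"""

from __future__ import annotations

from pathlib import Path

import yaml

from famkit.errors import FamkitError

DEFAULTS: dict = {
    "gc": 0.28,
    "sims": 2000,
    "seed": None,
    "tandem_window": 250_000,
    "gamma": 6.1e-9,
    "bootstrap": 1000,
    "support_threshold": 65.0,
    "neutral_tol": 0.05,
}


def load_config(path: str | Path | None = None) -> dict:
    """Built-in defaults, overridden by the YAML file when given."""
    config = dict(DEFAULTS)
    if path is None:
        return config
    with Path(path).open() as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise FamkitError(f"config {path}: expected a mapping of keys to scalars")
    unknown = set(loaded) - set(DEFAULTS)
    if unknown:
        raise FamkitError(f"config {path}: unknown keys {sorted(unknown)}")
    config.update(loaded)
    return config
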