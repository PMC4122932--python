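"""Flat key-value configuration files for model and simulation parameters.

Format: one ``key = value`` per line, ``#`` comments, blank lines ignored.
Documented keys (all optional, with model defaults):

  g, x                      microsatellite gradient and optimal allele size
  phi, step_p               mutation exponent and geometric step parameter
  rate_midpoint, rate_slope logistic rate-curve shape
  mu_min_fraction           floor rate as a fraction of the plateau rate
  min_size, max_size        allele-size support bounds
  s, h, mu_site             SNV selection/dominance coefficients and per-site
                            neutral mutation rate
"""

from __future__ import annotations

from pathlib import Path

from .models import MsatFitnessSurface, MsatMutationModel, SnvSelectionModel

_INT_KEYS = {"x", "phi", "min_size", "max_size"}
_FLOAT_KEYS = {"g", "step_p", "rate_midpoint", "rate_slope", "mu_min_fraction",
               "s", "h", "mu_site"}


def read_config(path: str | Path) -> dict:
    """Parse a flat key=value file into a typed dict."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        if key in _INT_KEYS:
            values[key] = int(value)
        elif key in _FLOAT_KEYS:
            values[key] = float(value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return values


def write_config(path: str | Path, values: dict) -> None:
    lines = [f"{key} = {values[key]}" for key in sorted(values)]
    Path(path).write_text("\n".join(lines) + "\n")


def models_from_config(values: dict):
    """Build (MsatFitnessSurface | None, MsatMutationModel, SnvSelectionModel | None)."""
    surface = None
    if "g" in values and "x" in values:
        surface = MsatFitnessSurface(optimum=values["x"], gradient=values["g"])
    msat_keys = {k: values[k] for k in
                 ("phi", "step_p", "rate_midpoint", "rate_slope",
                  "mu_min_fraction", "min_size", "max_size") if k in values}
    mutation = MsatMutationModel(**msat_keys)
    snv = None
    if "s" in values:
        snv_keys = {k: values[k] for k in ("s", "h", "mu_site") if k in values}
        snv = SnvSelectionModel(**snv_keys)
    return surface, mutation, snv
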