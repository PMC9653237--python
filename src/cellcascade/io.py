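"""Configuration parsing and result serialization.

A chain configuration is a YAML or JSON document: either a bare list of
compartment mappings or ``{"compartments": [...], "options": {...}}``.  Each
compartment is given either in probability form ``{p_b, p_d, p_e?, p_a?}``
(``p_e`` defaults to the complement) or in rate form
``{lambda, mu, nu}``; the two forms may not be mixed within one compartment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chain import CompartmentChain
from .core import ConfigError, FateProbs, ParameterError, Rates, TruncatedPMF

__all__ = [
    "ChainConfig",
    "parse_chain",
    "load_config",
    "write_config",
    "write_pmf_tsv",
    "read_pmf_tsv",
    "write_summary_json",
]

_PROB_KEYS = {"p_b", "p_d", "p_e", "p_a"}
_RATE_KEYS = {"lambda", "mu", "nu"}


@dataclass(frozen=True)
class ChainConfig:
    """Parsed chain plus free-form options (truncation, seed, paths...)."""

    chain: CompartmentChain
    options: dict = field(default_factory=dict)


def _parse_compartment(index: int, entry) -> tuple[FateProbs, Rates | None]:
    if not isinstance(entry, dict):
        raise ConfigError(f"compartment {index}: expected a mapping, got {entry!r}")
    keys = set(entry)
    has_prob = bool(keys & _PROB_KEYS)
    has_rate = bool(keys & _RATE_KEYS)
    if has_prob and has_rate:
        raise ConfigError(
            f"compartment {index}: probability and rate forms may not be mixed "
            f"(offending keys: {sorted(keys)})"
        )
    if not has_prob and not has_rate:
        raise ConfigError(
            f"compartment {index}: need either {{p_b, p_d, ...}} or "
            f"{{lambda, mu, nu}}, got keys {sorted(keys)}"
        )
    unknown = keys - _PROB_KEYS - _RATE_KEYS
    if unknown:
        raise ConfigError(f"compartment {index}: unknown fields {sorted(unknown)}")
    try:
        if has_rate:
            missing = _RATE_KEYS - keys
            if missing:
                raise ConfigError(
                    f"compartment {index}: rate form missing {sorted(missing)}"
                )
            rates = Rates(
                lam=float(entry["lambda"]), mu=float(entry["mu"]), nu=float(entry["nu"])
            )
            return FateProbs.from_rates(rates), rates
        fp = FateProbs(
            p_b=float(entry.get("p_b", 0.0)),
            p_d=float(entry.get("p_d", 0.0)),
            p_e=float(entry["p_e"]) if "p_e" in entry else None,
            p_a=float(entry.get("p_a", 0.0)),
        )
        return fp, None
    except ParameterError as err:
        raise ConfigError(f"compartment {index}: {err}") from err


def parse_chain(doc) -> ChainConfig:
    """Build a :class:`ChainConfig` from an already-loaded document."""
    if isinstance(doc, list):
        entries, options = doc, {}
    elif isinstance(doc, dict):
        entries = doc.get("compartments")
        options = dict(doc.get("options", {}))
        if entries is None:
            raise ConfigError("missing 'compartments' list")
    else:
        raise ConfigError(f"config root must be a list or mapping, got {doc!r}")
    if not entries:
        raise ConfigError("compartment list is empty")
    parsed = [_parse_compartment(i, e) for i, e in enumerate(entries)]
    fps = tuple(fp for fp, _ in parsed)
    rates = tuple(r for _, r in parsed)
    chain = CompartmentChain(fps, rates=rates if all(r is not None for r in rates) else None)
    return ChainConfig(chain=chain, options=options)


def load_config(path) -> ChainConfig:
    """Load a YAML/JSON chain configuration from disk."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: not valid YAML/JSON ({err})") from err
    return parse_chain(doc)


def write_config(cfg: ChainConfig, path) -> None:
    """Serialize a configuration so that load_config round-trips it."""
    comps = []
    for i, fp in enumerate(cfg.chain.compartments):
        if cfg.chain.rates is not None:
            r = cfg.chain.rates[i]
            comps.append({"lambda": r.lam, "mu": r.mu, "nu": r.nu})
        else:
            entry = {"p_b": fp.p_b, "p_d": fp.p_d, "p_e": fp.p_e}
            if fp.p_a:
                entry["p_a"] = fp.p_a
            comps.append(entry)
    doc = {"compartments": comps, "options": dict(cfg.options)}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def write_pmf_tsv(pmf: TruncatedPMF, path, header: dict | None = None) -> None:
    """Two-column TSV (k, probability) with parameters in '#' comments."""
    lines = []
    for key, value in (header or {}).items():
        lines.append(f"# {key} = {value!r}")
    lines.append(f"# tail_mass = {float(pmf.tail_mass)!r}")
    lines.append("k\tprobability")
    for k, p in enumerate(pmf.probs):
        lines.append(f"{k}\t{float(p)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf_tsv(path) -> TruncatedPMF:
    probs = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or line.startswith("k\t") or not line.strip():
            continue
        _, p = line.split("\t")
        probs.append(float(p))
    return TruncatedPMF(probs)


def write_summary_json(mapping: dict, path) -> None:
    """Stable-key JSON dump; numpy scalars coerced to plain floats/ints."""

    def _coerce(v):
        if hasattr(v, "item"):
            return v.item()
        if isinstance(v, dict):
            return {k: _coerce(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_coerce(x) for x in v]
        return v

    Path(path).write_text(json.dumps(_coerce(mapping), indent=2, sort_keys=True) + "\n")
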