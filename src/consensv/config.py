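"""YAML run configuration.

Example::

    genome: reference.fasta.fai      # or a list of {name, length}
    callers:
      - {name: delly2, vcf: calls/delly2.vcf}
      - {name: lumpy,  vcf: calls/lumpy.vcf}
    weights:
      insurveyor: {INS: 2}           # flat int or per-class map
    min_callers: {cnv: 2, inv: 2, ins: 2}
    max_gap: 100
    min_sv_len: 1
    caller_classes:                  # optional; enables threshold checks
      cnvnator: [DEL, DUP]
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .merge import MergeParams, default_weights, resolve_weight
from .model import SV_CLASSES, ConsensvError, GenomeInfo


class ConfigError(ConsensvError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    genome: GenomeInfo
    callers: list[tuple[str, str]]  # (name, vcf path)
    params: MergeParams
    min_sv_len: int = 1
    caller_classes: dict[str, frozenset[str]] = field(default_factory=dict)


def _load_genome(spec, base_dir: str) -> GenomeInfo:
    if isinstance(spec, str):
        path = spec if os.path.isabs(spec) else os.path.join(base_dir, spec)
        if not os.path.exists(path):
            raise ConfigError(f"genome: file not found: {path}")
        return GenomeInfo.from_fai(path)
    if isinstance(spec, list):
        try:
            return GenomeInfo.from_pairs((d["name"], d["length"]) for d in spec)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"genome: entries need 'name' and 'length' ({exc})") from exc
    raise ConfigError("genome: expected a FASTA-index path or a list of contigs")


def validate_thresholds(
    params: MergeParams,
    callers: list[str],
    caller_classes: dict[str, frozenset[str]],
) -> None:
    """Every class threshold must be attainable by the configured panel.

    Callers without an explicit class list are assumed able to call all
    four classes.
    """
    for sv_class in SV_CLASSES:
        able = [
            c for c in callers
            if sv_class in caller_classes.get(c, frozenset(SV_CLASSES))
        ]
        cap = sum(resolve_weight(params.weights, c, sv_class) for c in able)
        threshold = params.threshold_for(sv_class)
        field_name = {
            "DEL": "min_callers.cnv", "DUP": "min_callers.cnv",
            "INV": "min_callers.inv", "INS": "min_callers.ins",
        }[sv_class]
        if threshold > cap:
            raise ConfigError(
                f"{field_name}: threshold {threshold} exceeds the total weighted "
                f"support {cap} attainable for {sv_class} with the configured callers"
            )


def load_config(path: str) -> RunConfig:
    base_dir = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "genome" not in raw:
        raise ConfigError("genome: required")
    genome = _load_genome(raw["genome"], base_dir)
    callers_raw = raw.get("callers") or []
    if not callers_raw:
        raise ConfigError("callers: at least one caller VCF is required")
    callers: list[tuple[str, str]] = []
    for entry in callers_raw:
        try:
            name, vcf = entry["name"], entry["vcf"]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"callers: entries need 'name' and 'vcf' ({exc})") from exc
        vcf = vcf if os.path.isabs(vcf) else os.path.join(base_dir, vcf)
        if not os.path.exists(vcf):
            raise ConfigError(f"callers.{name}: file not found: {vcf}")
        callers.append((str(name), vcf))
    mc = raw.get("min_callers") or {}
    weights = raw.get("weights")
    params = MergeParams(
        min_callers_cnv=int(mc.get("cnv", 2)),
        min_callers_inv=int(mc.get("inv", 2)),
        min_callers_ins=int(mc.get("ins", 2)),
        max_gap=int(raw.get("max_gap", 100)),
        weights=weights if weights is not None else default_weights(),
    )
    caller_classes = {
        str(k): frozenset(str(c).upper() for c in v)
        for k, v in (raw.get("caller_classes") or {}).items()
    }
    validate_thresholds(params, [n for n, _ in callers], caller_classes)
    return RunConfig(
        genome=genome,
        callers=callers,
        params=params,
        min_sv_len=int(raw.get("min_sv_len", 1)),
        caller_classes=caller_classes,
    )
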