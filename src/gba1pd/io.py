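"""Readers/writers and pipeline configuration.

The VCF reader consumes per-platform callsets restricted to the GBA1 target
region (defaults to chr1:155,232,501-155,241,415 on GRCh38, 1-based
inclusive).  Phased genotypes (``|``) yield a per-haplotype phase group so
downstream code can name recombinant alleles; unphased calls leave the phase
empty.  Reports are emitted as TSV plus a JSON summary stamped with the
package version and a hash of the active configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

import gba1pd
from gba1pd.concordance import CallRecord, FilterConfig
from gba1pd.structure import ProximityConfig
from gba1pd.variants import GbaVariant

__all__ = [
    "PipelineConfig",
    "parse_region",
    "format_region",
    "load_config",
    "config_hash",
    "read_vcf_region",
    "write_report",
]

DEFAULT_REGION = ("chr1", 155_232_501, 155_241_415)

_REGION_RE = re.compile(r"^(\w+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse "chr1:155,232,501-155,241,415" (1-based, inclusive)."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed region: {text!r}")
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start > end:
        raise ValueError(f"region start after end: {text!r}")
    return m.group(1), start, end


def format_region(region: tuple[str, int, int]) -> str:
    chrom, start, end = region
    return f"{chrom}:{start:,}-{end:,}"


@dataclass
class PipelineConfig:
    region: tuple[str, int, int] = DEFAULT_REGION
    filter: FilterConfig = field(default_factory=FilterConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    early_onset_aao: float = 45.0
    early_onset_strict: bool = False
    simulation_config: Optional[str] = None
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"


_KNOWN_KEYS = {
    "region", "qual_min", "maf_nfe_max", "study_freq_max", "seq_window",
    "ca_cutoff", "early_onset_aao", "early_onset_strict", "simulation_config",
    "output_dir", "seed", "log_level",
}


def load_config(path: Optional[Path] = None, strict: bool = True) -> PipelineConfig:
    """Load a YAML pipeline config; absent keys fall back to defaults."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        message = f"unknown config keys: {sorted(unknown)}"
        if strict:
            raise ValueError(message)
        warnings.warn(message, stacklevel=2)
        raw = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    region = parse_region(raw["region"]) if "region" in raw else DEFAULT_REGION
    filt = FilterConfig(
        qual_min=raw.get("qual_min", 30.0),
        maf_nfe_max=raw.get("maf_nfe_max", 0.01),
        study_freq_max=raw.get("study_freq_max", 0.01),
        region=region,
    )
    prox = ProximityConfig(
        seq_window=raw.get("seq_window", 2), ca_cutoff=raw.get("ca_cutoff", 5.0)
    )
    return PipelineConfig(
        region=region,
        filter=filt,
        proximity=prox,
        early_onset_aao=raw.get("early_onset_aao", 45.0),
        early_onset_strict=raw.get("early_onset_strict", False),
        simulation_config=raw.get("simulation_config"),
        output_dir=raw.get("output_dir", "results"),
        seed=raw.get("seed", 0),
        log_level=raw.get("log_level", "INFO"),
    )


def dump_config(config: PipelineConfig, path: Path) -> None:
    payload = {
        "region": format_region(config.region),
        "qual_min": config.filter.qual_min,
        "maf_nfe_max": config.filter.maf_nfe_max,
        "study_freq_max": config.filter.study_freq_max,
        "seq_window": config.proximity.seq_window,
        "ca_cutoff": config.proximity.ca_cutoff,
        "early_onset_aao": config.early_onset_aao,
        "early_onset_strict": config.early_onset_strict,
        "simulation_config": config.simulation_config,
        "output_dir": config.output_dir,
        "seed": config.seed,
        "log_level": config.log_level,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_vcf_region(
    path: Path,
    region: tuple[str, int, int] = DEFAULT_REGION,
    platform: str = "",
) -> tuple[list[CallRecord], dict[str, int]]:
    """Read carrier calls from a VCF, keeping records inside the region.

    Multi-allelic sites are split per alternate allele.  Phased genotypes
    map each alternate allele to a ``sample:hapN`` phase group.  Returns the
    records and an audit dict (records outside the region, records skipped
    for missing genotypes).
    """
    from cyvcf2 import VCF

    chrom, start, end = region
    audit = {"outside_region": 0, "missing_gt": 0}
    records: list[CallRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for v in vcf:
        vchrom = v.CHROM if v.CHROM.startswith("chr") else f"chr{v.CHROM}"
        if vchrom != chrom or not start <= v.POS <= end:
            audit["outside_region"] += 1
            continue
        if v.genotypes is None or len(v.genotypes) != len(samples):
            warnings.warn(f"missing genotypes at {v.CHROM}:{v.POS}; skipped", stacklevel=2)
            audit["missing_gt"] += 1
            continue
        hgvs_p = v.INFO.get("HGVSP")
        maf = v.INFO.get("MAF_NFE")
        for sample, gt in zip(samples, v.genotypes):
            alleles, phased = gt[:-1], bool(gt[-1])
            for hap, allele in enumerate(alleles):
                if allele is None or allele <= 0:
                    continue
                alt = v.ALT[allele - 1]
                name = hgvs_p or f"{vchrom}:{v.POS}:{v.REF}>{alt}"
                variant = GbaVariant(
                    hgvs_p=hgvs_p,
                    hgvs_c=None if hgvs_p else name,
                    phase_group=f"{sample}:hap{hap + 1}" if phased else None,
                    maf_nfe=float(maf) if maf is not None else None,
                    qual=float(v.QUAL) if v.QUAL is not None else None,
                )
                records.append(
                    CallRecord(sample_id=sample, variant=variant, platform=platform,
                               chrom=vchrom, pos=v.POS)
                )
    return records, audit


def write_report(
    results: Mapping[str, object],
    out_dir: Path,
    config: Optional[PipelineConfig] = None,
) -> dict[str, Path]:
    """Write each result to TSV (DataFrames) or into a JSON summary.

    Returns the mapping of result name to written path; a ``summary.json``
    stamped with package version and config hash is always produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: dict[str, object] = {
        "package_version": gba1pd.__version__,
        "config_hash": config_hash(config) if config is not None else None,
    }
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            value.to_csv(path, sep="\t", index=False)
            written[name] = path
        else:
            summary[name] = value
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    written["summary"] = path
    return written
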