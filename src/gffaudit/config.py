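"""Tunable thresholds for the annotation auditor.

All classification thresholds live in one record so that a single YAML file
can reconfigure a run.  Defaults follow the curation conventions the tool
implements: a multiphasic extent shorter than 40 nt (stop codon included) is
reported as an alternative translation stop; extents longer than 63 nt
(>20 amino acids) are additionally marked as long overlaps.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import yaml


@dataclasses.dataclass
class AuditConfig:
    #: Multiphasic extents shorter than this (nt, stop codon included) are
    #: classified as alternative translation stops within a gene.
    multiphasic_short_nt: int = 40
    #: Multiphasic extents strictly longer than this (nt) are marked
    #: ``long_overlap`` (equivalent to more than 20 amino acids).
    long_overlap_nt: int = 63
    #: Regex anchored at the intron 5' end recognizing the minor-spliceosome
    #: (U12) donor consensus; covers both GT-AG and AT-AC U12 introns.
    u12_donor_pattern: str = "^[GA]TATCC"
    #: Junction calls with fewer supporting reads are culled as low frequency.
    junction_min_count: int = 2
    #: Junction calls with a lower confidence score are culled.
    junction_min_score: float = 0.0
    #: Maximum boundary displacement (nt) for reporting a junction as
    #: misaligned relative to an annotated intron.
    junction_window: int = 6
    #: Treat two genes as sharing a promoter when their 5'-most exon starts
    #: coincide exactly (the operational definition of a shared promoter).
    shared_promoter_exact: bool = True

    def u12_regex(self) -> re.Pattern[str]:
        return re.compile(self.u12_donor_pattern)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> AuditConfig:
    """Load an :class:`AuditConfig` from YAML; ``None`` gives the defaults.

    Unknown keys are rejected so that typos in a config file fail loudly.
    """
    if path is None:
        return AuditConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AuditConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return AuditConfig(**data)


def dump_config(config: AuditConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
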