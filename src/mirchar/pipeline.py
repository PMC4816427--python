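"""End-to-end characterization run: ingest -> dedup -> all censuses.

``run_characterization`` composes the module operations in a fixed order
and writes every table as TSV plus a JSON manifest (config hash, input
checksum, record counts per stage).  All analysis stages are
deterministic; randomness exists only in the synthetic generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from mirchar import composition, hairpin, library as lib, motifs, ssr
from mirchar.hairpin import DEFAULT_TETRALOOP_SET

logger = logging.getLogger("mirchar")


@dataclass
class RunConfig:
    input_path: str | None = None
    species_prefix: str | None = None
    pp_threshold: float = 0.70
    highly_rich_threshold: float = 0.90
    iim_motif: str = "UGUGU"
    gu_min_tract: int = 5
    ssr_min_repeats: int = 3
    ssr_max_unit: int = 5
    min_stem: int = 3
    loop_min: int = 3
    loop_max: int = 8
    allow_wobble: bool = True
    tetraloop_set: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_TETRALOOP_SET)
    )
    closing_pair_orientation: str = "unordered"  # "unordered" | "strict"
    output_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.pp_threshold < 1 or not 0 < self.highly_rich_threshold <= 1:
            raise ValueError("richness thresholds must lie in (0, 1]")
        if self.closing_pair_orientation not in ("unordered", "strict"):
            raise ValueError("closing_pair_orientation must be 'unordered' or 'strict'")
        if self.ssr_min_repeats < 2 or not 1 <= self.ssr_max_unit <= 5:
            raise ValueError("bad SSR parameters")
        if not 3 <= self.loop_min <= self.loop_max or self.min_stem < 1:
            raise ValueError("bad hairpin parameters")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ReportBundle:
    library: lib.MirnaLibrary
    length_dist: lib.LengthDistribution
    base_profile: composition.CompositionProfile
    pfm_five: composition.PositionalFrequencyMatrix
    pfm_three: composition.PositionalFrequencyMatrix
    pp_table: object  # pandas.DataFrame
    iim_census: list
    gu_rich: list
    ssr_tracts: list
    ssr_totals: ssr.SSRSummary
    hairpins: list
    cascade: dict
    manifest: dict


def _input_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_characterization(
    config: RunConfig, library: lib.MirnaLibrary | None = None
) -> ReportBundle:
    """Run every census over one deduplicated library snapshot.

    Pass either ``config.input_path`` (a FASTA file) or an in-memory
    ``library`` (e.g. from the synthetic generator).
    """
    config.validate()
    if library is None:
        if config.input_path is None:
            raise ValueError("need input_path or an in-memory library")
        library = lib.read_fasta(config.input_path, config.species_prefix)
        checksum = _input_checksum(config.input_path)
    else:
        checksum = "in-memory"
    logger.info("ingested %d records from %s", len(library), library.source)

    deduped = lib.deduplicate(library)
    logger.info("deduplicated: %d unique sequences", len(deduped))
    if not deduped.records:
        raise ValueError("library is empty after filtering/deduplication")

    dist = lib.length_distribution(deduped)
    profile = composition.base_content(deduped)
    pfm5 = composition.positional_frequency(deduped, composition.Anchor.FIVE_PRIME)
    pfm3 = composition.positional_frequency(deduped, composition.Anchor.THREE_PRIME)
    pp_table = composition.classify_pp_library(
        deduped, config.pp_threshold, config.highly_rich_threshold
    )
    iim = motifs.find_iim(deduped, config.iim_motif)
    logger.info("IIM census: %d records carry %s", len(iim), config.iim_motif)
    gu_rich = [
        (rec, motifs.gu_tracts(rec, config.gu_min_tract))
        for rec in deduped.records
        if motifs.is_gu_rich(rec, config.gu_min_tract)
    ]
    tracts = [
        t
        for rec in deduped.records
        for t in ssr.find_ssrs(rec, config.ssr_min_repeats, config.ssr_max_unit)
    ]
    totals = ssr.ssr_summary(deduped, config.ssr_min_repeats, config.ssr_max_unit)
    logger.info("SSR census: %d tracts (%.2f per miRNA)", totals.grand_total, totals.grand_relative)
    best = [
        (rec, h)
        for rec in deduped.records
        if (
            h := hairpin.best_hairpin(
                rec, config.min_stem, config.loop_min, config.loop_max, config.allow_wobble
            )
        )
        is not None
    ]
    cascade = hairpin.tetraloop_cascade(
        deduped,
        motif_set=config.tetraloop_set,
        min_stem=config.min_stem,
        loop_min=config.loop_min,
        loop_max=config.loop_max,
        allow_wobble=config.allow_wobble,
        strict_orientation=config.closing_pair_orientation == "strict",
    )

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "input_checksum": checksum,
        "n_input_records": len(library),
        "n_unique": len(deduped),
        "n_iim": len(iim),
        "n_gu_rich": len(gu_rich),
        "n_ssr_tracts": totals.grand_total,
        "n_foldable": len(best),
    }
    return ReportBundle(
        library=deduped,
        length_dist=dist,
        base_profile=profile,
        pfm_five=pfm5,
        pfm_three=pfm3,
        pp_table=pp_table,
        iim_census=iim,
        gu_rich=gu_rich,
        ssr_tracts=tracts,
        ssr_totals=totals,
        hairpins=best,
        cascade=cascade,
        manifest=manifest,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write every table of the bundle under ``out_dir``; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib.write_summary_tsv(bundle.library, out / "library.tsv")
    lib.write_summary_json(bundle.library, out / "library.json")
    composition.write_composition_tsv(bundle.base_profile, out / "composition.tsv")
    composition.write_pfm_tsv(bundle.pfm_five, out / "pfm_five_prime.tsv")
    composition.write_pfm_tsv(bundle.pfm_three, out / "pfm_three_prime.tsv")
    bundle.pp_table.to_csv(out / "pp_classification.tsv", sep="\t", index=False)
    motifs.write_iim_census_tsv(bundle.iim_census, out / "iim_census.tsv")
    all_gu = [t for _, tl in bundle.gu_rich for t in tl]
    motifs.write_gu_tracts_tsv(all_gu, out / "gu_tracts.tsv")
    ssr.write_tracts_tsv(bundle.ssr_tracts, out / "ssr_tracts.tsv")
    ssr.write_summary_tsv(bundle.ssr_totals, out / "ssr_summary.tsv")
    hairpin.write_hairpins_tsv(bundle.hairpins, out / "hairpins.tsv")
    hairpin.write_cascade_tsv(bundle.cascade, out / "tetraloop_cascade.tsv")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2) + "\n")
    return out
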