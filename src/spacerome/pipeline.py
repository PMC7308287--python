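"""Orchestration of the four-way comparison from a config file to report
tables: real and mock spacers against the virome and against each spacer's
own (array-masked) host genome, plus an optional scrambled control,
enrichment/depletion ratio curves, bootstrap ranges, per-group pooling and
an optional PAM table.

All randomness flows from a single master seed split deterministically per
stage, so a run regenerates bit-identically from the same config + seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .controls import mock_spacers_for, scramble_spacers
from .kmers import MatchCurve, TargetSet, match_indicators
from .pam import PamTable, pam_table
from .seqs import (
    GenomeWithArrays,
    SpacerRecord,
    dedup_spacers,
    flag_short_spacers,
    load_fasta,
    load_intervals,
    load_spacer_counts,
    load_spacers_fasta,
)
from .stats import BootstrapRange, RatioCurve, curve_bootstrap_ranges, \
    ranges_nonoverlap, ratio_curve

logger = logging.getLogger("spacerome")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # (genome_id, fasta path, arrays path or None)
    genomes: list[tuple[str, str, str | None]]
    spacers_path: str
    virome_path: str
    spacers_format: str = "fasta"  # or "counts"
    k_min: int = 8
    k_max: int = 22
    controls: tuple[str, ...] = ("mock", "scrambled")
    B: int = 1000
    seed: int = 0
    weighted: bool = False
    pam: bool = False
    pam_reference: str = "virome"  # or "host"
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ConfigError(f"need 1 <= k_min <= k_max, got "
                              f"{self.k_min}..{self.k_max}")
        for c in self.controls:
            if c not in ("mock", "scrambled"):
                raise ConfigError(f"unknown control {c!r}")
        if self.pam_reference not in ("virome", "host"):
            raise ConfigError("pam_reference must be 'virome' or 'host'")

    @property
    def k_values(self) -> tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1))


def parse_config(path: str | Path) -> RunConfig:
    """Flat key=value config; `genome=` may repeat as id:fasta[:arrays]."""
    kv: dict[str, str] = {}
    genomes: list[tuple[str, str, str | None]] = []
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}: line {lineno}: expected key=value")
            key, val = (x.strip() for x in line.split("=", 1))
            if key == "genome":
                parts = val.split(":")
                if len(parts) < 2:
                    raise ConfigError(
                        f"{path}: line {lineno}: genome=id:fasta[:arrays]")
                genomes.append(
                    (parts[0], parts[1],
                     parts[2] if len(parts) > 2 and parts[2] else None))
            elif key == "group":
                gid, label = val.split(":", 1)
                groups[gid] = label
            else:
                kv[key] = val
    if not genomes:
        raise ConfigError(f"{path}: at least one genome= line required")
    if "spacers" not in kv or "virome" not in kv:
        raise ConfigError(f"{path}: spacers= and virome= are required")
    return RunConfig(
        genomes=genomes,
        spacers_path=kv["spacers"],
        virome_path=kv["virome"],
        spacers_format=kv.get("spacers_format", "fasta"),
        k_min=int(kv.get("k_min", 8)),
        k_max=int(kv.get("k_max", 22)),
        controls=tuple(c for c in kv.get("controls", "mock,scrambled").split(",") if c),
        B=int(kv.get("B", 1000)),
        seed=int(kv.get("seed", 0)),
        weighted=kv.get("weighted", "false").lower() in ("1", "true", "yes"),
        pam=kv.get("pam", "false").lower() in ("1", "true", "yes"),
        pam_reference=kv.get("pam_reference", "virome"),
        groups=groups,
    )


@dataclass
class RunReport:
    config_digest: str
    seed: int
    version: str
    curves: dict[str, MatchCurve]
    ratios: dict[str, RatioCurve]
    ranges: dict[str, list[BootstrapRange]]
    group_curves: dict[str, dict[str, MatchCurve]] = field(default_factory=dict)
    pam: PamTable | None = None
    short_spacers: list[str] = field(default_factory=list)

    def provenance(self) -> str:
        return (f"# spacerome v{self.version} config_sha256={self.config_digest} "
                f"seed={self.seed}")


def _stage_seeds(seed: int, n: int) -> list[int]:
    # deterministic per-stage 31-bit seeds derived from the master seed
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def _curve_from_indicators(
    ind: np.ndarray, counts: np.ndarray, k_values: Sequence[int],
    spacer_set_id: str, target_set_id: str, weighted: bool,
) -> MatchCurve:
    m = (ind * counts[:, None]).sum(axis=0)
    curve = MatchCurve(
        spacer_set_id=spacer_set_id, target_set_id=target_set_id,
        k_values=tuple(int(k) for k in k_values), m_per_k=m,
        N=float(counts.sum()), weighted=weighted,
        indicators=ind, counts=counts,
    )
    curve.validate()
    return curve


def _self_indicators(
    spacers: Sequence[SpacerRecord],
    genomes: dict[str, GenomeWithArrays],
    k_values: Sequence[int],
    exclude_source: bool,
) -> np.ndarray:
    """Each spacer searched against its own (array-masked) source genome."""
    ind = np.zeros((len(spacers), len(k_values)), dtype=bool)
    by_genome: dict[str, list[int]] = {}
    for i, sp in enumerate(spacers):
        if sp.genome_id not in genomes:
            raise ConfigError(
                f"spacer {sp.spacer_id or sp.seq[:12]!r} references unknown "
                f"genome {sp.genome_id!r}")
        by_genome.setdefault(sp.genome_id, []).append(i)
    for gid, idxs in by_genome.items():
        tgt = TargetSet.from_genome(genomes[gid])
        sub = [spacers[i] for i in idxs]
        ind[np.array(idxs)] = match_indicators(
            sub, tgt, k_values, exclude_source=exclude_source)
    return ind


def run_analysis(
    config: RunConfig,
    genomes: dict[str, GenomeWithArrays] | None = None,
    spacers: list[SpacerRecord] | None = None,
    virome: TargetSet | None = None,
) -> RunReport:
    """Compute the four-way report (spacers/mocks x virome/self, plus the
    scrambled-vs-virome control when requested).

    Pre-loaded objects may be passed to bypass file I/O; otherwise they are
    loaded from the config paths.
    """
    if genomes is None:
        genomes = {}
        for gid, fasta, arrays in config.genomes:
            seqs = load_fasta(fasta)
            ivs = load_intervals(arrays) if arrays else []
            genomes[gid] = GenomeWithArrays(gid, seqs, ivs)
    if virome is None:
        virome = TargetSet.from_sequences("virome", load_fasta(config.virome_path))
    if spacers is None:
        loader = (load_spacer_counts if config.spacers_format == "counts"
                  else load_spacers_fasta)
        spacers = loader(config.spacers_path)
        only = next(iter(genomes)) if len(genomes) == 1 else None
        for sp in spacers:
            if not sp.genome_id:
                if only is None:
                    raise ConfigError(
                        "spacers must carry genome ids when several genomes "
                        "are loaded")
                sp.genome_id = only
    if not spacers:
        raise ConfigError("empty spacer set")
    spacers = dedup_spacers(spacers)
    short = flag_short_spacers(spacers, config.k_max)
    if short:
        logger.info("flagged %d spacers shorter than k_max=%d",
                    len(short), config.k_max)

    kv = config.k_values
    counts = np.array(
        [sp.count if config.weighted else 1 for sp in spacers], dtype=np.int64)
    seeds = _stage_seeds(config.seed, 4)

    curves: dict[str, MatchCurve] = {}
    ind_real_v = match_indicators(spacers, virome, kv)
    curves["spacers|virome"] = _curve_from_indicators(
        ind_real_v, counts, kv, "spacers", "virome", config.weighted)
    ind_real_s = _self_indicators(spacers, genomes, kv, exclude_source=False)
    curves["spacers|self"] = _curve_from_indicators(
        ind_real_s, counts, kv, "spacers", "self", config.weighted)

    mocks: list[SpacerRecord] = []
    if "mock" in config.controls:
        by_genome: dict[str, list[SpacerRecord]] = {}
        for sp in spacers:
            by_genome.setdefault(sp.genome_id, []).append(sp)
        for gi, (gid, group) in enumerate(sorted(by_genome.items())):
            mocks.extend(
                mock_spacers_for(genomes[gid], group, seeds[0] + gi))
        ones = np.ones(len(mocks), dtype=np.int64)  # mock set taken as is
        ind_mock_v = match_indicators(mocks, virome, kv)
        curves["mocks|virome"] = _curve_from_indicators(
            ind_mock_v, ones, kv, "mocks", "virome", False)
        ind_mock_s = _self_indicators(mocks, genomes, kv, exclude_source=True)
        curves["mocks|self"] = _curve_from_indicators(
            ind_mock_s, ones, kv, "mocks", "self", False)

    if "scrambled" in config.controls:
        scr = scramble_spacers(spacers, seeds[1])
        ind_scr_v = match_indicators(scr, virome, kv)
        curves["scrambled|virome"] = _curve_from_indicators(
            ind_scr_v, counts, kv, "scrambled", "virome", config.weighted)

    ratios: dict[str, RatioCurve] = {}
    if "mock" in config.controls:
        ratios["virus"] = ratio_curve(curves["spacers|virome"],
                                      curves["mocks|virome"])
        ratios["self"] = ratio_curve(curves["spacers|self"],
                                     curves["mocks|self"])
    if "scrambled" in config.controls:
        ratios["virus_vs_scrambled"] = ratio_curve(
            curves["spacers|virome"], curves["scrambled|virome"])

    ranges = {
        name: curve_bootstrap_ranges(curve, config.B, seeds[2])
        for name, curve in curves.items()
    }

    group_curves: dict[str, dict[str, MatchCurve]] = {}
    if config.groups:
        labels = sorted(set(config.groups.values()))
        for label in labels:
            gids = {g for g, lab in config.groups.items() if lab == label}
            idx = np.array(
                [i for i, sp in enumerate(spacers) if sp.genome_id in gids],
                dtype=np.int64)
            if idx.size == 0:
                continue
            group_curves[label] = {
                "spacers|virome": _curve_from_indicators(
                    ind_real_v[idx], counts[idx], kv,
                    f"spacers[{label}]", "virome", config.weighted),
                "spacers|self": _curve_from_indicators(
                    ind_real_s[idx], counts[idx], kv,
                    f"spacers[{label}]", "self", config.weighted),
            }

    pam: PamTable | None = None
    if config.pam:
        if config.pam_reference == "virome":
            ref = virome.sequences
        else:
            ref = [s for g in genomes.values() for s in g.sequences]
        pam = pam_table(spacers, ref, weighted=True)

    digest = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    for c in curves.values():
        logger.info("curve %s|%s: N=%g m=%s", c.spacer_set_id,
                    c.target_set_id, c.N, c.m_per_k.tolist())
    return RunReport(
        config_digest=digest, seed=config.seed, version=__version__,
        curves=curves, ratios=ratios, ranges=ranges,
        group_curves=group_curves, pam=pam, short_spacers=short,
    )


# ---------------------------------------------------------------------------
# report serialization (tab-separated, provenance header, deterministic)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / "curves.tsv"
    with open(p, "w") as fh:
        fh.write(report.provenance() + "\n")
        fh.write("spacer_set_id\ttarget_set_id\tk\tm\tN\tfraction\n")
        all_curves = list(report.curves.items()) + [
            (f"{label}:{name}", c)
            for label, d in report.group_curves.items()
            for name, c in d.items()
        ]
        for _, c in all_curves:
            for j, k in enumerate(c.k_values):
                fh.write(
                    f"{c.spacer_set_id}\t{c.target_set_id}\t{k}\t"
                    f"{_fmt(float(c.m_per_k[j]))}\t{_fmt(c.N)}\t"
                    f"{_fmt(float(c.fraction_per_k[j]))}\n")
    written.append(p)

    p = outdir / "ratios.tsv"
    with open(p, "w") as fh:
        fh.write(report.provenance() + "\n")
        fh.write("comparison\tnumerator\tdenominator\tk\tratio\n")
        for name, rc in report.ratios.items():
            for j, k in enumerate(rc.k_values):
                fh.write(f"{name}\t{rc.numerator_id}\t{rc.denominator_id}\t"
                         f"{k}\t{_fmt(float(rc.ratio_per_k[j]))}\n")
    written.append(p)

    if ("spacers|virome" in report.ranges
            and "mocks|virome" in report.ranges):
        p = outdir / "enrichment.tsv"
        with open(p, "w") as fh:
            fh.write(report.provenance() + "\n")
            fh.write("target\tk\treal_fraction\tcontrol_fraction\tratio\t"
                     "real_lo\treal_hi\tcontrol_lo\tcontrol_hi\t"
                     "nonoverlap\tB\tseed\n")
            for side, real_key, ctrl_key in (
                ("virome", "spacers|virome", "mocks|virome"),
                ("self", "spacers|self", "mocks|self"),
            ):
                real = report.curves[real_key]
                ctrl = report.curves[ctrl_key]
                for j, k in enumerate(real.k_values):
                    ra = report.ranges[real_key][j]
                    rb = report.ranges[ctrl_key][j]
                    fh.write("\t".join([
                        side, str(k),
                        _fmt(float(real.fraction_per_k[j])),
                        _fmt(float(ctrl.fraction_per_k[j])),
                        _fmt(float(real.fraction_per_k[j]
                                   / ctrl.fraction_per_k[j])),
                        _fmt(ra.lo), _fmt(ra.hi), _fmt(rb.lo), _fmt(rb.hi),
                        str(int(ranges_nonoverlap(ra, rb))),
                        str(ra.B), str(ra.seed),
                    ]) + "\n")
        written.append(p)

    if report.pam is not None:
        p = outdir / "pam.tsv"
        with open(p, "w") as fh:
            fh.write(report.provenance()
                     + f" pam_window_start={report.pam.window_start}"
                     + f" pam_total={_fmt(report.pam.total)}\n")
            fh.write("pam\tweighted_count\tfraction\n")
            total = report.pam.total
            for pam_seq in sorted(report.pam.counts):
                c = report.pam.counts[pam_seq]
                fh.write(f"{pam_seq}\t{_fmt(c)}\t"
                         f"{_fmt(c / total if total else 0.0)}\n")
        written.append(p)
    return written


def summarize_arrays(
    genomes: dict[str, GenomeWithArrays] | Sequence[GenomeWithArrays],
    spacers: Sequence[SpacerRecord],
) -> pd.DataFrame:
    """Convenience: spacer counts per (genome, array)."""
    if isinstance(genomes, dict):
        glist = list(genomes.values())
    else:
        glist = list(genomes)
    rows = []
    for g in glist:
        for ai, _iv in enumerate(g.arrays):
            aid = f"arr{ai}"
            n = sum(1 for sp in spacers
                    if sp.genome_id == g.genome_id and sp.array_id == aid)
            rows.append({"genome_id": g.genome_id, "array_id": aid,
                         "n_spacers": n})
    return pd.DataFrame(rows, columns=["genome_id", "array_id", "n_spacers"])
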