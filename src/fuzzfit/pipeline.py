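"""Umbrella pipeline: shifts -> relaxation -> titration, with one summary.

Each stage consumes the documented TSV/NMR-STAR inputs named in the run
configuration and emits per-stage TSVs plus entries in a JSON summary that
embeds the configuration, its hash and the seed, so reruns with an equal
configuration are byte-identical.  A stage failure is reported under its
stage name and downstream stages are skipped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import relaxation, secondary_shifts, titration
from .constructs import get_construct
from .io import RunConfig, read_peak_tsv, read_shift_star, read_titration, write_tsv

log = logging.getLogger("fuzzfit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_shifts(path: str):
    if str(path).endswith((".str", ".star")):
        return read_shift_star(path)
    return read_peak_tsv(path, "shifts")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dict."""
    stages = {
        "shifts": config.shifts_path,
        "relaxation": config.decay_path or config.noe_path,
        "titration": config.titration_path,
    }
    if not any(stages.values()):
        raise ValueError("empty configuration: no stage inputs given")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    construct = get_construct(config.construct_id)
    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        summary["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
        summary["failed_stage"] = stage
        log.error("stage %s failed: %s", stage, exc)

    # --- shifts ----------------------------------------------------------
    if config.shifts_path:
        try:
            observed = _read_shifts(config.shifts_path)
            reference = secondary_shifts.load_random_coil(config.reference)
            if config.extend:
                observed = secondary_shifts.extend_assignments(
                    observed, construct
                )
            profile = secondary_shifts.secondary_shift(
                observed, reference, sequence=construct
            )
            call = secondary_shifts.classify_disorder(
                profile, run_length=config.run_length
            )
            write_tsv(
                profile.data,
                out_dir / "secondary_shifts.tsv",
                {"seed": config.seed, "config_hash": config.config_hash(),
                 "reference": reference.name},
            )
            summary["stages"]["shifts"] = {
                "reference": reference.name,
                "n_defined": int(profile.defined().shape[0]),
                "disordered": call.disordered,
                "n_runs": len(call.runs),
                "runs": [[r.start, r.end, r.sign] for r in call.runs],
            }
        except Exception as exc:  # noqa: BLE001 - reported per stage
            fail("shifts", exc)
            return _finish(summary, out_dir)

    # --- relaxation ------------------------------------------------------
    if config.decay_path or config.noe_path:
        try:
            stage: dict = {}
            if config.decay_path:
                series = read_peak_tsv(config.decay_path, "decay")
                rates = relaxation.fit_rates(series)
                write_tsv(rates, out_dir / "rates.tsv",
                          {"seed": config.seed})
                ratio = relaxation.r2_over_r1(rates)
                if not ratio.empty:
                    write_tsv(ratio, out_dir / "r2_over_r1.tsv",
                              {"seed": config.seed})
                stage["n_rates"] = int(len(rates))
                for kind in ("R1", "R2"):
                    sub = rates[rates["rate_kind"] == kind]
                    if not sub.empty:
                        stage[f"median_{kind}"] = float(sub["rate"].median())
            if config.noe_path:
                noe = read_peak_tsv(config.noe_path, "noe")
                taus = relaxation.tau_profile(noe)
                write_tsv(taus, out_dir / "tau_n.tsv", {"seed": config.seed})
                ok = taus[taus["flag"] == ""]
                stage["tau_n_median_ns"] = float(ok["tau_n_ns"].median())
                stage["tau_n_by_field_ns"] = {
                    str(f): float(sub["tau_n_ns"].median())
                    for f, sub in ok.groupby("field_mhz")
                }
            summary["stages"]["relaxation"] = stage
        except Exception as exc:  # noqa: BLE001
            fail("relaxation", exc)
            return _finish(summary, out_dir)

    # --- titration -------------------------------------------------------
    if config.titration_path:
        try:
            if not config.r0_path:
                raise ValueError("titration stage needs r0_path (free-state R2)")
            series = read_titration(config.titration_path, config.r0_path)
            fit = titration.fit_binding(
                series, "FSFG", n_sites=config.n_sites,
                kd_bounds=config.kd_bounds, keep_surface=False,
            )
            stage = {"FSFG": fit.summary()}
            if config.per_group:
                for g in series.groups():
                    if g in ("FSFG", "spacer"):
                        continue
                    try:
                        gf = titration.fit_binding(
                            series, g, n_sites=1,
                            kd_bounds=config.kd_bounds, keep_surface=False,
                        )
                        stage[g] = gf.summary()
                    except titration.NonIdentifiableError as exc:
                        stage[g] = {"error": str(exc)}
            summary["stages"]["titration"] = stage
        except Exception as exc:  # noqa: BLE001
            fail("titration", exc)
            return _finish(summary, out_dir)

    return _finish(summary, out_dir)


def _finish(summary: dict, out_dir: Path) -> dict:
    path = out_dir / "summary.json"
    path.write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
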