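"""End-to-end orchestration: checks -> assembly -> correction -> output.

This is what the ``mdvflux run`` command executes; it is separated from the
CLI so that scripts and tests can drive the whole workflow in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .correction import apply_corrections
from .export_flux import (
    ReplicateSummary,
    make_groups,
    replicate_stats,
    write_ftbl_ms,
    write_openflux_csv,
    write_summary_tsv,
)
from .io_tabular import (
    AssemblyFeedback,
    RawTable,
    RunConfig,
    assemble_fragments,
    read_config,
    read_fragment_library,
    read_isotope_table,
    read_measurement_table,
    read_obm_table,
    read_replicate_names,
    write_dataset,
    write_feedback_mask,
)
from .isotopes import ElementIsotopeTable, default_isotope_table
from .model import Dataset, FragmentDefinition, builtin_library
from .qc import LabelingReport, QCMask, run_checks, summarize_labeling

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run", "run_from_config"]


@dataclass
class PipelineResult:
    """Everything one run produced.  ``status`` is 'clean' or 'flagged';
    a flagged run without force stops before correction and leaves the
    corrected fields empty."""

    status: str
    mask: Optional[QCMask] = None
    rt_mask: Optional[QCMask] = None
    assembly_feedback: List[AssemblyFeedback] = field(default_factory=list)
    corrected: Optional[Dataset] = None
    correction_messages: List[str] = field(default_factory=list)
    summaries: List[ReplicateSummary] = field(default_factory=list)
    labeling: Optional[LabelingReport] = None
    written: List[Path] = field(default_factory=list)


def run(
    raw: RawTable,
    config: RunConfig,
    library: Optional[Sequence[FragmentDefinition]] = None,
    rt_table: Optional[RawTable] = None,
    obm: Optional[Dict[str, float]] = None,
    group_names: Optional[Sequence[str]] = None,
    isotope_table: Optional[ElementIsotopeTable] = None,
    out_dir: Optional[str | Path] = None,
    force: bool = False,
) -> PipelineResult:
    """Run checks, correction and export over an in-memory raw table.

    Any flagged cell terminates the run before correction (feedback masks are
    still written) unless ``force`` is set.
    """
    if library is None:
        library = builtin_library()
    if isotope_table is None:
        isotope_table = default_isotope_table()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    result = PipelineResult(status="clean")
    mask, rt_mask = run_checks(raw, config, rt_table)
    result.mask, result.rt_mask = mask, rt_mask
    n_flagged = mask.n_flagged + (rt_mask.n_flagged if rt_mask else 0)
    if n_flagged:
        result.status = "flagged"
        if out is not None:
            if mask.n_flagged:
                write_feedback_mask(mask, out / "feedback_measurements.tsv")
                result.written.append(out / "feedback_measurements.tsv")
            if rt_mask and rt_mask.n_flagged:
                write_feedback_mask(rt_mask, out / "feedback_retention_times.tsv")
                result.written.append(out / "feedback_retention_times.tsv")
        if not force:
            log.warning("%d cells flagged; terminating before correction", n_flagged)
            return result
        log.warning("%d cells flagged; continuing (force)", n_flagged)

    dataset, feedback = assemble_fragments(raw, library, config)
    result.assembly_feedback = feedback
    corrected, messages = apply_corrections(dataset, config, obm, isotope_table)
    result.corrected = corrected
    result.correction_messages = messages

    groups = make_groups(
        config.groups_for(corrected.n_chromatograms), group_names
    )
    result.labeling = summarize_labeling(corrected, groups)
    result.summaries = replicate_stats(corrected, groups)

    if out is not None:
        if "tsv" in config.output_formats:
            write_dataset(corrected, out / "corrected.tsv")
            write_summary_tsv(result.summaries, out / "replicate_summary.tsv")
            result.written += [out / "corrected.tsv", out / "replicate_summary.tsv"]
        if "ftbl_ms" in config.output_formats:
            result.written += write_ftbl_ms(
                result.summaries, out, "mass-spectrometry",
                model_file=config.ftbl_model_file,
            )
        if "ftbl_label" in config.output_formats:
            result.written += write_ftbl_ms(
                result.summaries, out, "label-measurements",
                model_file=None,
            )
        if "openflux" in config.output_formats:
            result.written += write_openflux_csv(result.summaries, out)
        result.labeling.write(out / "average_labeling.tsv")
        result.written.append(out / "average_labeling.tsv")
        if feedback:
            text = "\n".join(fb.message for fb in feedback) + "\n"
            (out / "assembly_feedback.txt").write_text(text)
            result.written.append(out / "assembly_feedback.txt")
    return result


def run_from_config(
    config_path: str | Path,
    out_dir: str | Path,
    data_file: Optional[str | Path] = None,
    force: bool = False,
) -> PipelineResult:
    """Load everything named in a configuration file and run the pipeline.

    Relative file names in the configuration are resolved against the
    configuration file's directory; ``data_file`` overrides the configured
    measurement file.
    """
    config_path = Path(config_path)
    config = read_config(config_path)
    base = config_path.parent

    def resolve(name: Optional[str]) -> Optional[Path]:
        if name is None:
            return None
        p = Path(name)
        return p if p.is_absolute() else base / p

    data_path = Path(data_file) if data_file else resolve(config.data_file)
    raw = read_measurement_table(data_path)
    rt_table = (
        read_measurement_table(resolve(config.rt_file)) if config.rt_file else None
    )
    obm = read_obm_table(resolve(config.obm_file)) if config.obm_file else None
    names = (
        read_replicate_names(resolve(config.group_names_file))
        if config.group_names_file
        else None
    )
    library = builtin_library()
    if config.fragments_file:
        library = read_fragment_library(resolve(config.fragments_file))
    isotable = (
        read_isotope_table(resolve(config.isotope_table_file))
        if config.isotope_table_file
        else None
    )
    if config.ftbl_model_file:
        config.ftbl_model_file = str(resolve(config.ftbl_model_file))
    return run(
        raw, config, library=library, rt_table=rt_table, obm=obm,
        group_names=names, isotope_table=isotable, out_dir=out_dir, force=force,
    )
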