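"""Shared fixtures: references, panels, and one full pipeline run per session."""

import pytest

from taurhap import (DamageParams, PanelSet, DiagnosticPanel, DiagnosticVariant,
                     apply_panel_refs, default_panels, make_reference)
from taurhap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def panels():
    return default_panels()


@pytest.fixture(scope="session")
def ref16k(panels):
    """Synthetic circular mitogenome with panel ref alleles imposed."""
    ref = make_reference(16338, 0.4, 7)
    ref, _ = apply_panel_refs(ref, panels)
    return ref


@pytest.fixture(scope="session")
def mini_panels():
    """Small panel set on a 3 kb frame for fast read-level closed loops."""
    return PanelSet([
        DiagnosticPanel("root", variants=(
            DiagnosticVariant(500, "A", "G"),
            DiagnosticVariant(1200, "C", "T"),
        )),
        DiagnosticPanel("A1", parent="root", variants=(
            DiagnosticVariant(800, "G", "A"),
            DiagnosticVariant(2100, "T", "C"),
        )),
        DiagnosticPanel("B1", parent="root", variants=(
            DiagnosticVariant(900, "C", "T"),
            DiagnosticVariant(2600, "A", "G"),
        )),
    ])


@pytest.fixture(scope="session")
def mini_ref(mini_panels):
    ref = make_reference(3000, 0.45, 11)
    ref, _ = apply_panel_refs(ref, mini_panels)
    return ref


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """One full default pipeline run (21 specimens, 30x, 16,338 bp) shared by
    the end-to-end checks."""
    outdir = tmp_path_factory.mktemp("cohort_run")
    config = PipelineConfig(outdir=str(outdir), seed=1)
    summary = run_pipeline(config)
    return outdir, summary
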