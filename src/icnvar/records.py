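"""Subject-level phenotype records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict


GROUP_PATIENT = "adhd"
GROUP_CONTROL = "control"


@dataclass
class SubjectRecord:
    """Demographics and covariates for one subject.

    ``sex`` is "M" or "F"; the diagnostic model encodes male as 1 and
    female as 0.  ``mean_fd`` is the mean framewise displacement in mm,
    the head-motion covariate; it may be absent until motion QC has run.
    """

    subject_id: str
    group: str
    sex: str
    age: float
    viq: float
    piq: float
    fiq: float
    mean_fd: float | None = None

    @property
    def label(self) -> int:
        """Diagnostic label: 1 for a patient, 0 for a control."""
        return 1 if self.group == GROUP_PATIENT else 0

    @property
    def sex_code(self) -> int:
        return 1 if self.sex.upper().startswith("M") else 0

    def to_dict(self) -> dict:
        return asdict(self)
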