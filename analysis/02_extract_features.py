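"""Extract DWT descriptors and time-domain features from the cohort waveforms.

Reads results/waveforms.csv (written by 01_simulate_cohort.py), applies the
inclusion rules (a-wave > 1 μV; electrode not more than 2 mm below the
reference), computes the Haar-DWT band/window energy descriptors (a20, a40,
b20, b40, op80, op160), %OPs and the time-domain a-/b-wave measures for every
recording, and writes features.tsv + qc.tsv.
"""

from pathlib import Path

from ergdwt.pipeline import StudyConfig, extract_feature_table
from ergdwt.waveform_io import read_waveforms

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = read_waveforms(OUT / "waveforms.csv")
    cfg = StudyConfig()
    features, qc = extract_feature_table(study, cfg)
    features.to_csv(OUT / "features.tsv", sep="\t", index=False, float_format="%.6g")
    qc.to_csv(OUT / "qc.tsv", sep="\t", index=False)
    print(
        f"extracted features for {len(features)} of {len(qc)} recordings "
        f"({qc['passed'].mean():.1%} passed QC) -> {OUT / 'features.tsv'}"
    )


if __name__ == "__main__":
    main()
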