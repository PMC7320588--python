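"""Generate the synthetic baseline cohort used by the downstream analyses.

Draws a cohort of 142 subjects (the baseline sample size) from the
calibrated generator and writes the five analysis tables plus the latent
ground truth under results/data/.
"""

from pathlib import Path

from neurocohort.synthetic import generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 17
N = 142


def main() -> None:
    cohort = generate_cohort(seed=SEED, n_subjects=N)
    cohort.save(OUT)
    print(f"synthetic cohort: n={N}, seed={SEED}")
    print(f"  subjects with lesions : {cohort.lesions['subject_id'].nunique()}")
    print(f"  PET subset            : {len(cohort.pet)}")
    print(f"  tables written to     : {OUT}")


if __name__ == "__main__":
    main()
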