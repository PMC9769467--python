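"""Risk-triage the 15 release variables from the packaged expert ratings.

Writes the key/sensitive/implicit classification and per-variable total
scores to results/triage.json.  With the shipped ratings the key variables
are the five demographic/recruitment attributes (age group, gender, quarter
and year of first diagnosis, cohort).
"""

import json
from pathlib import Path

from pufkit import default_triage

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    result = default_triage()
    payload = {
        "key_variables": sorted(result.key_variables),
        "sensitive_variables": sorted(result.sensitive_variables),
        "implicit_variables": sorted(result.implicit_variables),
        "scores": dict(sorted(result.scores.items())),
    }
    (OUT / "triage.json").write_text(json.dumps(payload, indent=2))
    print(f"key variables ({len(result.key_variables)}): "
          f"{', '.join(sorted(result.key_variables))}")
    print(f"implicitly protected: {', '.join(sorted(result.implicit_variables))}")
    print(f"wrote {OUT/'triage.json'}")


if __name__ == "__main__":
    main()
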