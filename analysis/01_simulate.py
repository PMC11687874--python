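"""Generate the synthetic five-month vaccine-discourse stream.

Emits the event stream (JSON Lines) and the latent-stance ground truth
(sidecar CSV, never merged into the stream) under scratch/.  The defaults
are the stated world: 2000 users, June–October 2021, neutral→pro drift with
a small, vocal, homophilous anti minority.

    python analysis/01_simulate.py [--seed N] [--n-users N] [--out-dir scratch]
"""

import argparse
from pathlib import Path

from stanceform import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-users", type=int, default=2000)
    ap.add_argument("--out-dir", type=Path, default=Path("scratch"))
    args = ap.parse_args()

    cfg = sd.SimConfig(n_users=args.n_users, seed=args.seed)
    res = sd.simulate_stream(cfg)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    stream_path = args.out_dir / "stream.jsonl"
    truth_path = args.out_dir / "truth.csv"
    sd.write_stream(res.events, stream_path)
    sd.write_truth(res.truth, truth_path)

    n_react = sum(1 for e in res.events if e.reaction is not None)
    n_url = sum(1 for e in res.events if e.shared_url is not None)
    print(f"wrote {len(res.events)} events -> {stream_path}")
    print(f"  reactions: {n_react}  shared urls: {n_url}")
    print(f"wrote latent ground truth -> {truth_path}")


if __name__ == "__main__":
    main()
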