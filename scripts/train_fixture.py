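"""Regenerate the bundled pretrained test checkpoint.

Trains a 32-unit agent with the package's default hyperparameters for long
enough that the planning effects emerge (order 10^6 episodes; hours on one
CPU), then writes it as JSON shards under tests/fixtures/, each kept below
64 kB, with weights rounded to 4 significant digits.

Usage: python scripts/train_fixture.py --batches 60000 --seed 4242 \
           --out tests/fixtures
"""

import argparse
import json
import os

import numpy as np


def save_sharded(params, out_dir: str, stem: str = "agent_fixture",
                 max_bytes: int = 60_000, digits: int = 3) -> list[str]:
    """Write params as JSON shards of bounded size; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    from dataclasses import asdict

    def enc(arr):
        return [float(f"{x:.{digits}g}") for x in np.asarray(arr).ravel()]

    items = [("config", asdict(params.config))]
    items += [(k, enc(v)) for k, v in sorted(params.tensors.items())]
    shards, cur, cur_size = [], {}, 2
    for key, val in items:
        piece = len(json.dumps({key: val})) + 2
        if cur and cur_size + piece > max_bytes:
            shards.append(cur)
            cur, cur_size = {}, 2
        cur[key] = val
        cur_size += piece
    if cur:
        shards.append(cur)
    paths = []
    for i, shard in enumerate(shards):
        blob = {"tensors": {}}
        for k, v in shard.items():
            if k == "config":
                blob["config"] = v
            else:
                blob["tensors"][k] = v
        path = os.path.join(out_dir, f"{stem}_shard{i}.json")
        with open(path, "w") as f:
            json.dump(blob, f)
        paths.append(path)
    return paths


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--batches", type=int, default=60_000)
    ap.add_argument("--seed", type=int, default=4242)
    ap.add_argument("--hidden", type=int, default=32)
    ap.add_argument("--out", type=str, default="tests/fixtures")
    ap.add_argument("--from-checkpoint", type=str, default=None,
                    help="skip training; shard an existing checkpoint")
    args = ap.parse_args()
    from replan.agent import AgentConfig, AgentParams
    from replan.training import TrainConfig, train

    if args.from_checkpoint:
        params = AgentParams.load(args.from_checkpoint)
    else:
        params, _ = train(AgentConfig(hidden_units=args.hidden),
                          TrainConfig(batches=args.batches, seed=args.seed))
    paths = save_sharded(params, args.out)
    for p in paths:
        print(f"{p}: {os.path.getsize(p)} bytes")


if __name__ == "__main__":
    main()
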