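#!/usr/bin/env python
"""Optional: behavioral statistics from a locally downloaded cage archive.

The deposited multi-cage behavioral text archives (and the real-trial
decoding traces) are external downloads; this script never fetches them.
Point it at an already-downloaded directory of per-cage text logs and it
recomputes the same-mouse averaged median inter-headfix interval and the
night-time headfix fraction with the package's parsers.  The expected
dialect of the archive differs from the package's native log layout;
adjust --delimiter/--field-order (and extend the event map in
mesocage.eventlog.Dialect) after inspecting the downloaded files.

Usage:
    python scripts/archive_stats.py --archive /path/to/cage_logs \
        --delimiter $'\\t' --field-order 0,1,2,3
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from mesocage.behavior_stats import day_night_fraction, interval_stats
from mesocage.eventlog import Dialect, EventStore, parse_sessions, read_log


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--archive", type=Path, required=True,
                        help="directory of downloaded cage text logs")
    parser.add_argument("--glob", default="*.txt")
    parser.add_argument("--delimiter", default="\t")
    parser.add_argument("--field-order", default="0,1,2,3",
                        help="positions of timestamp,tag,event,payload")
    args = parser.parse_args()

    order = tuple(int(x) for x in args.field_order.split(","))
    dialect = Dialect(delimiter=args.delimiter, field_order=order)

    per_cage = {}
    for path in sorted(args.archive.glob(args.glob)):
        store = EventStore(read_log(path, dialect))
        sessions = parse_sessions(store)
        iv = interval_stats(sessions, definition="gap")
        per_cage[path.name] = {
            "n_sessions": len(sessions),
            "avg_same_mouse_median_interval_s": iv.avg_same_median,
            "cross_mouse_median_interval_s": iv.cross_median,
            "night_fraction_pct": 100.0 * day_night_fraction(sessions),
        }
    if not per_cage:
        raise SystemExit(f"no files matching {args.glob!r} under {args.archive}")
    print(json.dumps(per_cage, indent=2))


if __name__ == "__main__":
    main()
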