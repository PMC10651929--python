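"""Independent brute-force oracles, written in plain Python against the
documented contracts (not against the implementation)."""

import math
import statistics

EARTH_R = 6_371_000.0


def hav(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = math.radians(lat2 - lat1), math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_R * math.asin(math.sqrt(a))


def stay_oracle(points, d_roam=50.0, min_duration_min=5.0, min_events=2):
    """Greedy maximal consecutive runs satisfying the centroid-radius predicate.

    ``points`` is a list of (t_minutes, lat, lon). Returns a list of
    (start_min, end_min, centroid_lat, centroid_lon, n) tuples.
    """

    def fits(run):
        clat = statistics.median(p[1] for p in run)
        clon = statistics.median(p[2] for p in run)
        return all(hav(p[1], p[2], clat, clon) < d_roam for p in run)

    stays, run = [], []
    for p in points:
        if not run or fits(run + [p]):
            run.append(p)
        else:
            stays.append(run)
            run = [p]
    if run:
        stays.append(run)

    out = []
    for run in stays:
        if len(run) < min_events or run[-1][0] - run[0][0] < min_duration_min:
            continue
        out.append(
            (
                run[0][0],
                run[-1][0],
                statistics.median(p[1] for p in run),
                statistics.median(p[2] for p in run),
                len(run),
            )
        )
    return out


def nearest_poi_oracle(stay_pts, poi_pts, d_max=200.0):
    """All-pairs nearest neighbor: list of (poi_index or None, dist or None).

    ``poi_pts`` must be ordered by ascending poi id; ties pick the first.
    """
    out = []
    for slat, slon in stay_pts:
        best_i, best_d = None, None
        for i, (plat, plon) in enumerate(poi_pts):
            d = hav(slat, slon, plat, plon)
            if best_d is None or d < best_d:
                best_i, best_d = i, d
        if best_d is not None and best_d < d_max:
            out.append((best_i, best_d))
        else:
            out.append((None, None))
    return out


def night_minutes_oracle(start_min, end_min, night=(22.0, 6.0)):
    """Minute-resolution tally of [start, end] minutes inside the nightly
    22:00-06:00 window; times in minutes from an arbitrary midnight."""
    total = 0
    for m in range(int(start_min), int(end_min)):
        hod = (m / 60.0) % 24.0
        if hod >= night[0] or hod < night[1]:
            total += 1
    return total
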