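"""Independent brute-force recount of (drug, SOC) events from the raw files.

Deliberately shares no code with the package: its own normalization, its own
token matching, its own dedup and mapping, written as plain nested loops.
Used as the ground-truth oracle the pipeline must agree with exactly.
"""

from collections import Counter


def _norm(text):
    out = " ".join(text.lower().split())
    return out.strip(" .,;:!?()[]{}'\"-_/\\")


def _tokens(text):
    out = []
    cur = []
    for ch in _norm(text):
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def _read(path, delim):
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    header = lines[0].split(delim)
    rows = []
    for ln in lines[1:]:
        fields = ln.split(delim)
        if len(fields) == len(header):
            rows.append(fields)
    return rows


def brute_force_counts(demo_path, drug_path, reac_path, lexicon_path,
                       dictionary_path, delimiter="$"):
    """Return (overall Counter[(drug_id, soc)], Counter[(drug_id, soc, stratum)])."""
    # dictionary: term -> soc (LLTs resolved through their parent PT)
    dict_rows = _read(dictionary_path, "\t")
    pt_soc = {}
    llt_parent = {}
    for term, level, parent, soc in dict_rows:
        if level == "PT":
            pt_soc[_norm(term)] = soc
        else:
            llt_parent[_norm(term)] = _norm(parent)
    term_soc = dict(pt_soc)
    for llt, parent in llt_parent.items():
        term_soc[llt] = pt_soc[parent]

    # lexicon: synonym token tuples -> drug_id
    syn_map = {}
    for row in _read(lexicon_path, "\t"):
        drug_id, _preferred, synonyms = row[0], row[1], row[2]
        for syn in synonyms.split("|"):
            toks = tuple(_tokens(syn))
            if toks:
                syn_map[toks] = drug_id

    def match(text):
        toks = _tokens(text)
        hits = set()
        for syn_toks, drug_id in syn_map.items():
            k = len(syn_toks)
            for i in range(len(toks) - k + 1):
                if tuple(toks[i:i + k]) == syn_toks:
                    hits.add(drug_id)
                    break
        return hits

    # assemble reports
    sex = {}
    drugs = {}
    reacs = {}
    order = []
    for caseid, ver, sx in _read(demo_path, delimiter):
        key = (caseid, int(ver))
        if key not in sex and key not in drugs and key not in reacs and key not in order:
            order.append(key)
        sex.setdefault(key, sx)
    for caseid, ver, role, name in _read(drug_path, delimiter):
        key = (caseid, int(ver))
        if key not in sex and key not in drugs and key not in reacs:
            if key not in order:
                order.append(key)
        drugs.setdefault(key, []).append((role, name))
    for caseid, ver, pt in _read(reac_path, delimiter):
        key = (caseid, int(ver))
        if key not in sex and key not in drugs and key not in reacs:
            if key not in order:
                order.append(key)
        if pt:
            reacs.setdefault(key, []).append(pt)
    all_keys = []
    seen = set()
    for key in order + list(sex) + list(drugs) + list(reacs):
        if key not in seen:
            seen.add(key)
            all_keys.append(key)

    # completeness filter
    complete = []
    for key in all_keys:
        caseid, _ver = key
        if caseid and drugs.get(key) and reacs.get(key):
            complete.append(key)

    # dedup: same (case id, drug-name set, reaction set) -> highest version,
    # tie -> latest in input order
    groups = {}
    for pos, key in enumerate(complete):
        caseid, ver = key
        gkey = (
            caseid,
            frozenset(_norm(n) for _r, n in drugs[key]),
            frozenset(_norm(t) for t in reacs[key]),
        )
        cur = groups.get(gkey)
        if cur is None or ver > cur[0] or (ver == cur[0] and pos > cur[1]):
            groups[gkey] = (ver, pos, key)
    kept = [key for _v, _p, key in groups.values()]

    overall = Counter()
    stratified = Counter()
    for key in kept:
        matched = set()
        for role, name in drugs[key]:
            if role in ("PS", "SS"):
                matched |= match(name)
        unique_terms = []
        seen_terms = set()
        for t in reacs[key]:
            n = _norm(t)
            if n and n not in seen_terms:
                seen_terms.add(n)
                unique_terms.append(n)
        sx = sex.get(key)
        stratum = "female" if sx == "F" else "male" if sx == "M" else "excluded"
        for drug_id in matched:
            for term in unique_terms:
                soc = term_soc.get(term)
                if soc is not None:
                    overall[(drug_id, soc)] += 1
                    stratified[(drug_id, soc, stratum)] += 1
    return overall, stratified
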