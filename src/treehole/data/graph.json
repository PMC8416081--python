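{
  "comment": "Synthetic fixture knowledge graph. Surface forms are invented placeholder tokens that preserve the computational structure (hierarchy, multi-word forms, overlapping forms) without distributing a real risk lexicon. Users with appropriate ethics approval drop in their own graph file.",
  "ontologies": [
    {
      "ontology": "suicide",
      "roots": ["suicideMethod", "suicidePlan"],
      "concepts": [
        {"id": "suicide", "label": "suicide", "surface_forms": [], "parents": []},
        {"id": "suicideMethod", "label": "suicide method", "surface_forms": [], "parents": ["suicide"]},
        {"id": "suicidePlan", "label": "suicide plan", "surface_forms": [], "parents": ["suicide"]},
        {"id": "wristMethod", "label": "wrist-cutting method (synthetic form)", "surface_forms": ["veinmark", "redline cut"], "parents": ["suicideMethod"]},
        {"id": "charcoalMethod", "label": "charcoal-burning method (synthetic form)", "surface_forms": ["ashfume", "grey smolder"], "parents": ["suicideMethod"]},
        {"id": "overdoseMethod", "label": "overdose method (synthetic form)", "surface_forms": ["pillheap", "double pillheap"], "parents": ["suicideMethod"]},
        {"id": "procurePlan", "label": "procurement plan (synthetic form)", "surface_forms": ["stockpile run", "gatherkit"], "parents": ["suicidePlan"]},
        {"id": "partnerPlan", "label": "partner-meeting plan (synthetic form)", "surface_forms": ["pactmeet", "covenant call"], "parents": ["suicidePlan"]}
      ]
    },
    {
      "ontology": "time",
      "roots": ["future", "present", "past"],
      "concepts": [
        {"id": "time", "label": "time", "surface_forms": [], "parents": []},
        {"id": "future", "label": "future", "surface_forms": [], "parents": ["time"]},
        {"id": "present", "label": "present", "surface_forms": [], "parents": ["time"]},
        {"id": "past", "label": "past", "surface_forms": [], "parents": ["time"]},
        {"id": "tonightTerm", "label": "tonight", "surface_forms": ["tonight"], "parents": ["future"]},
        {"id": "tomorrowTerm", "label": "tomorrow", "surface_forms": ["tomorrow", "next dawn"], "parents": ["future"]},
        {"id": "soonTerm", "label": "soon", "surface_forms": ["soonfall"], "parents": ["future"]},
        {"id": "nowTerm", "label": "right now", "surface_forms": ["right now", "at once"], "parents": ["present"]},
        {"id": "pastTerm", "label": "past reference", "surface_forms": ["last winter", "yesterday"], "parents": ["past"]}
      ]
    },
    {
      "ontology": "space",
      "roots": ["spacePlace"],
      "concepts": [
        {"id": "spacePlace", "label": "place", "surface_forms": [], "parents": []},
        {"id": "bridgeSite", "label": "bridge site (synthetic form)", "surface_forms": ["far bridge"], "parents": ["spacePlace"]},
        {"id": "roofSite", "label": "rooftop site (synthetic form)", "surface_forms": ["high ledge"], "parents": ["spacePlace"]}
      ]
    },
    {
      "ontology": "wish",
      "roots": ["suicideWish"],
      "concepts": [
        {"id": "suicideWish", "label": "subjective suicidal wish", "surface_forms": [], "parents": []},
        {"id": "departWish", "label": "wish to depart (synthetic form)", "surface_forms": ["wishfade", "endlonging"], "parents": ["suicideWish"]},
        {"id": "farewellWish", "label": "farewell wish (synthetic form)", "surface_forms": ["lastletter", "farewell letter"], "parents": ["suicideWish"]}
      ]
    }
  ]
}
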