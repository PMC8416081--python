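{
  "comment": "Default distant-supervision rule set. Only the level-8 pair follows the published logic-program template verbatim; the other levels extend the same free_text/concept alternation to the published level criteria and are marked extrapolated.",
  "rules": [
    {
      "rule_id": "L9_method_future",
      "level": 9,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicideMethod", "ontology": "suicide"},
        {"kind": "free_text"},
        {"kind": "concept", "root": "future", "ontology": "time"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L9_future_method",
      "level": 9,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "future", "ontology": "time"},
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicideMethod", "ontology": "suicide"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L8_time_plan",
      "level": 8,
      "extrapolated": false,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "future", "ontology": "time"},
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicidePlan", "ontology": "suicide"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L8_plan_time",
      "level": 8,
      "extrapolated": false,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicidePlan", "ontology": "suicide"},
        {"kind": "free_text"},
        {"kind": "concept", "root": "future", "ontology": "time"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L7_method",
      "level": 7,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicideMethod", "ontology": "suicide"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L6_plan",
      "level": 6,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicidePlan", "ontology": "suicide"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L5_wish_future",
      "level": 5,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicideWish", "ontology": "wish"},
        {"kind": "free_text"},
        {"kind": "concept", "root": "future", "ontology": "time"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L5_future_wish",
      "level": 5,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "future", "ontology": "time"},
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicideWish", "ontology": "wish"},
        {"kind": "free_text"}
      ]
    },
    {
      "rule_id": "L4_wish",
      "level": 4,
      "extrapolated": true,
      "slots": [
        {"kind": "free_text"},
        {"kind": "concept", "root": "suicideWish", "ontology": "wish"},
        {"kind": "free_text"}
      ]
    }
  ]
}
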