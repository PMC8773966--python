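{
  "$defs": {
    "BinSummary": {
      "properties": {
        "edges": {
          "items": {
            "type": "number"
          },
          "title": "Edges",
          "type": "array"
        },
        "counts": {
          "items": {
            "type": "integer"
          },
          "title": "Counts",
          "type": "array"
        },
        "percentages": {
          "items": {
            "type": "number"
          },
          "title": "Percentages",
          "type": "array"
        }
      },
      "required": [
        "edges",
        "counts",
        "percentages"
      ],
      "title": "BinSummary",
      "type": "object"
    },
    "CategorySummary": {
      "properties": {
        "n": {
          "title": "N",
          "type": "integer"
        },
        "min": {
          "title": "Min",
          "type": "number"
        },
        "max": {
          "title": "Max",
          "type": "number"
        },
        "mean": {
          "title": "Mean",
          "type": "number"
        },
        "sd": {
          "title": "Sd",
          "type": "number"
        }
      },
      "required": [
        "n",
        "min",
        "max",
        "mean",
        "sd"
      ],
      "title": "CategorySummary",
      "type": "object"
    },
    "CutoffSummary": {
      "properties": {
        "threshold": {
          "title": "Threshold",
          "type": "number"
        },
        "sensitivity": {
          "title": "Sensitivity",
          "type": "number"
        },
        "specificity": {
          "title": "Specificity",
          "type": "number"
        },
        "youden_j": {
          "title": "Youden J",
          "type": "number"
        }
      },
      "required": [
        "threshold",
        "sensitivity",
        "specificity",
        "youden_j"
      ],
      "title": "CutoffSummary",
      "type": "object"
    },
    "OverlapSummary": {
      "properties": {
        "low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Low"
        },
        "high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "High"
        },
        "count_inside": {
          "title": "Count Inside",
          "type": "integer"
        },
        "fraction_inside": {
          "title": "Fraction Inside",
          "type": "number"
        }
      },
      "required": [
        "low",
        "high",
        "count_inside",
        "fraction_inside"
      ],
      "title": "OverlapSummary",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        },
        "config": {
          "additionalProperties": true,
          "title": "Config",
          "type": "object"
        },
        "package": {
          "default": "spectsuv",
          "title": "Package",
          "type": "string"
        },
        "version": {
          "default": "",
          "title": "Version",
          "type": "string"
        }
      },
      "title": "Provenance",
      "type": "object"
    },
    "RegionRow": {
      "properties": {
        "count": {
          "title": "Count",
          "type": "integer"
        },
        "percent": {
          "title": "Percent",
          "type": "number"
        }
      },
      "required": [
        "count",
        "percent"
      ],
      "title": "RegionRow",
      "type": "object"
    },
    "RocSummary": {
      "properties": {
        "auc": {
          "title": "Auc",
          "type": "number"
        },
        "ci_low": {
          "title": "Ci Low",
          "type": "number"
        },
        "ci_high": {
          "title": "Ci High",
          "type": "number"
        }
      },
      "required": [
        "auc",
        "ci_low",
        "ci_high"
      ],
      "title": "RocSummary",
      "type": "object"
    }
  },
  "description": "Full cohort analysis: summaries through overlap, plus provenance.",
  "properties": {
    "summaries": {
      "additionalProperties": {
        "$ref": "#/$defs/CategorySummary"
      },
      "title": "Summaries",
      "type": "object"
    },
    "regions": {
      "additionalProperties": {
        "$ref": "#/$defs/RegionRow"
      },
      "title": "Regions",
      "type": "object"
    },
    "shapiro_p": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Shapiro P",
      "type": "object"
    },
    "mann_whitney_u": {
      "title": "Mann Whitney U",
      "type": "number"
    },
    "mann_whitney_p": {
      "title": "Mann Whitney P",
      "type": "number"
    },
    "roc": {
      "$ref": "#/$defs/RocSummary"
    },
    "cutoff": {
      "$ref": "#/$defs/CutoffSummary"
    },
    "bins": {
      "additionalProperties": {
        "$ref": "#/$defs/BinSummary"
      },
      "title": "Bins",
      "type": "object"
    },
    "overlap": {
      "$ref": "#/$defs/OverlapSummary"
    },
    "n_unlabeled_excluded": {
      "default": 0,
      "title": "N Unlabeled Excluded",
      "type": "integer"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "summaries",
    "regions",
    "shapiro_p",
    "mann_whitney_u",
    "mann_whitney_p",
    "roc",
    "cutoff",
    "bins",
    "overlap",
    "provenance"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
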