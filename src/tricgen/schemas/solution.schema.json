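{
  "$defs": {
    "OverlapGroupReport": {
      "properties": {
        "members": {
          "items": {
            "type": "integer"
          },
          "title": "Members",
          "type": "array"
        },
        "edges": {
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "integer"
              },
              {
                "type": "integer"
              }
            ],
            "type": "array"
          },
          "title": "Edges",
          "type": "array"
        }
      },
      "required": [
        "members",
        "edges"
      ],
      "title": "OverlapGroupReport",
      "type": "object"
    },
    "TriclusterReport": {
      "properties": {
        "id": {
          "title": "Id",
          "type": "integer"
        },
        "size": {
          "maxItems": 3,
          "minItems": 3,
          "prefixItems": [
            {
              "type": "integer"
            },
            {
              "type": "integer"
            },
            {
              "type": "integer"
            }
          ],
          "title": "Size",
          "type": "array"
        },
        "n_cells": {
          "title": "N Cells",
          "type": "integer"
        },
        "rows": {
          "items": {
            "type": "integer"
          },
          "title": "Rows",
          "type": "array"
        },
        "cols": {
          "items": {
            "type": "integer"
          },
          "title": "Cols",
          "type": "array"
        },
        "ctxs": {
          "items": {
            "type": "integer"
          },
          "title": "Ctxs",
          "type": "array"
        },
        "row_pattern": {
          "title": "Row Pattern",
          "type": "string"
        },
        "col_pattern": {
          "title": "Col Pattern",
          "type": "string"
        },
        "ctx_pattern": {
          "title": "Ctx Pattern",
          "type": "string"
        },
        "temporal_profile": {
          "title": "Temporal Profile",
          "type": "string"
        },
        "plaid": {
          "title": "Plaid",
          "type": "string"
        },
        "pct_missing": {
          "title": "Pct Missing",
          "type": "number"
        },
        "pct_noise": {
          "title": "Pct Noise",
          "type": "number"
        },
        "pct_errors": {
          "title": "Pct Errors",
          "type": "number"
        }
      },
      "required": [
        "id",
        "size",
        "n_cells",
        "rows",
        "cols",
        "ctxs",
        "row_pattern",
        "col_pattern",
        "ctx_pattern",
        "temporal_profile",
        "plaid",
        "pct_missing",
        "pct_noise",
        "pct_errors"
      ],
      "title": "TriclusterReport",
      "type": "object"
    }
  },
  "description": "Serializable ground truth for one generated dataset.",
  "properties": {
    "dims": {
      "maxItems": 3,
      "minItems": 3,
      "prefixItems": [
        {
          "type": "integer"
        },
        {
          "type": "integer"
        },
        {
          "type": "integer"
        }
      ],
      "title": "Dims",
      "type": "array"
    },
    "dataset_type": {
      "title": "Dataset Type",
      "type": "string"
    },
    "n_triclusters": {
      "title": "N Triclusters",
      "type": "integer"
    },
    "coverage": {
      "title": "Coverage",
      "type": "number"
    },
    "pct_missing": {
      "title": "Pct Missing",
      "type": "number"
    },
    "pct_noise": {
      "title": "Pct Noise",
      "type": "number"
    },
    "pct_errors": {
      "title": "Pct Errors",
      "type": "number"
    },
    "triclusters": {
      "items": {
        "$ref": "#/$defs/TriclusterReport"
      },
      "title": "Triclusters",
      "type": "array"
    },
    "overlap_groups": {
      "default": [],
      "items": {
        "$ref": "#/$defs/OverlapGroupReport"
      },
      "title": "Overlap Groups",
      "type": "array"
    }
  },
  "required": [
    "dims",
    "dataset_type",
    "n_triclusters",
    "coverage",
    "pct_missing",
    "pct_noise",
    "pct_errors",
    "triclusters"
  ],
  "title": "SolutionReport",
  "type": "object"
}
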