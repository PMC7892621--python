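design_id: validation_replication
rng_seed: null
arms:
  - arm_id: main
    allocation_percent: 100.0
    starting_balance: 1000.0
    end_message: >-
      The session is over. Remember that in real-life gambling the house
      always wins, and that strategies learned here will not transfer.
    blocks:
      - game_type: card
        n_trials: 40
        bet_size: 10.0
        bet_returned_on_win: false
        show_balance: true
        options:
          - option_id: deck_left
            win_probability: 0.45
            win_amount: 20.0
          - option_id: deck_right
            win_probability: 0.45
            win_amount: 20.0
      - game_type: slot
        n_trials: 40
        bet_size: 10.0
        bet_returned_on_win: false
        show_balance: true
        themes:
          - theme_id: S1
            display_probability: 0.5
            win_probability: 0.5
            win_amount: 20.0
          - theme_id: S2
            display_probability: 0.5
            win_probability: 0.2
            win_amount: 20.0
      - game_type: card
        n_trials: 16
        bet_size: 10.0
        bet_returned_on_win: false
        show_balance: true
        options:
          - option_id: deck_left
            win_probability: 0.0
            win_amount: 20.0
          - option_id: deck_right
            win_probability: 0.0
            win_amount: 20.0
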