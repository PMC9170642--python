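"""Optional interactive renderers (require the ``display`` extra: pygame).

Visual conventions: blue user disc, solid red filled hazards, red-outline
unfilled hazards, a start screen awaiting a mouse click, and a feedback
screen showing the trial's survival time.
"""

from __future__ import annotations

from attnbattery.kinematics import Vector2D
from attnbattery.moa import MOAConfig, init_trial, step
from attnbattery.mot import MOTConfig, begin_movement, init_mot_trial, step_mot
from attnbattery.seeding import TASK_CODES, derive_seed


def _require_pygame():
    try:
        import pygame
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "interactive display requires pygame; install with "
            "'pip install attnbattery[display]'"
        ) from exc
    return pygame


def _wait_for_click(pygame, screen, font, message: str) -> bool:  # pragma: no cover
    screen.fill((0, 0, 0))
    text = font.render(message, True, (255, 255, 255))
    screen.blit(text, text.get_rect(center=screen.get_rect().center))
    pygame.display.flip()
    while True:
        event = pygame.event.wait()
        if event.type == pygame.QUIT:
            return False
        if event.type == pygame.MOUSEBUTTONDOWN:
            return True


def run_moa_interactive(config: MOAConfig) -> None:  # pragma: no cover
    """Mouse-controlled avoidance trials with start and feedback screens."""
    pygame = _require_pygame()
    pygame.init()
    screen = pygame.display.set_mode((int(config.window.width), int(config.window.height)))
    pygame.display.set_caption("Multiple Object Avoidance")
    font = pygame.font.Font(None, 36)
    clock = pygame.time.Clock()
    n_total = config.n_practice_trials + config.n_recorded_trials
    try:
        for i in range(n_total):
            if not _wait_for_click(pygame, screen, font, f"Trial {i + 1}/{n_total}: click to start"):
                return
            state = init_trial(config, derive_seed(config.master_seed, TASK_CODES["MOA"], i))
            while not state.terminated:
                for event in pygame.event.get():
                    if event.type == pygame.QUIT:
                        return
                mx, my = pygame.mouse.get_pos()
                step(state, Vector2D(float(mx), float(my)), config)
                screen.fill((0, 0, 0))
                for hz in state.hazards:
                    pos = (int(hz.disc.center.x), int(hz.disc.center.y))
                    if hz.filled:
                        pygame.draw.circle(screen, (220, 30, 30), pos, int(hz.disc.radius))
                    else:
                        pygame.draw.circle(screen, (220, 30, 30), pos, int(hz.disc.radius), width=2)
                pygame.draw.circle(
                    screen,
                    (40, 90, 230),
                    (int(state.user.center.x), int(state.user.center.y)),
                    int(state.user.radius),
                )
                pygame.display.flip()
                clock.tick(round(1.0 / config.tick))
            if not _wait_for_click(
                pygame, screen, font, f"Survived {state.survival_time:.2f} s — click to continue"
            ):
                return
    finally:
        pygame.quit()


def run_mot_interactive(config: MOTConfig) -> None:  # pragma: no cover
    """Clickable tracking trials: flash phase, movement, then selection."""
    pygame = _require_pygame()
    pygame.init()
    screen = pygame.display.set_mode((int(config.window.width), int(config.window.height)))
    pygame.display.set_caption("Multiple Object Tracking")
    font = pygame.font.Font(None, 36)
    clock = pygame.time.Clock()
    half = config.square_side / 2.0

    def draw(state, highlight: set[int], selected: set[int]) -> None:
        screen.fill((0, 0, 0))
        for idx, (center, _, _) in enumerate(state.squares):
            rect = pygame.Rect(
                int(center.x - half), int(center.y - half), int(config.square_side), int(config.square_side)
            )
            color = (240, 240, 60) if idx in highlight else (200, 200, 200)
            if idx in selected:
                color = (60, 220, 60)
            pygame.draw.rect(screen, color, rect)
        pygame.display.flip()

    try:
        total_correct = 0
        for i in range(config.n_trials):
            if not _wait_for_click(pygame, screen, font, f"Trial {i + 1}/{config.n_trials}: click to start"):
                return
            state = init_mot_trial(config, derive_seed(config.master_seed, TASK_CODES["MOT"], i))
            flash_ticks = round(config.flash_duration / config.tick)
            for tick_i in range(flash_ticks):
                on = (tick_i // max(1, flash_ticks // 10)) % 2 == 0
                draw(state, state.target_indices if on else set(), set())
                clock.tick(round(1.0 / config.tick))
            begin_movement(state)
            while state.phase == "moving":
                for event in pygame.event.get():
                    if event.type == pygame.QUIT:
                        return
                step_mot(state, config)
                draw(state, set(), set())
                clock.tick(round(1.0 / config.tick))
            selected: set[int] = set()
            while len(selected) < config.n_targets:
                event = pygame.event.wait()
                if event.type == pygame.QUIT:
                    return
                if event.type == pygame.MOUSEBUTTONDOWN:
                    mx, my = event.pos
                    for idx, (center, _, _) in enumerate(state.squares):
                        if abs(center.x - mx) <= half and abs(center.y - my) <= half:
                            selected.add(idx)
                draw(state, set(), selected)
            n_correct = len(selected & state.target_indices)
            total_correct += n_correct
            if not _wait_for_click(
                pygame, screen, font, f"{n_correct}/{config.n_targets} correct — click to continue"
            ):
                return
    finally:
        pygame.quit()
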